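"""EM: expectation statistics, constrained M-step updates, fit driver."""

import numpy as np
import pytest

from mphmm import (
    EMConfig,
    StimulusEmbeddingSpec,
    StimulusResponsePair,
    build_mn_template,
    e_step,
    em_fit,
    m_step,
    validate_model,
)
from mphmm.learning import initialize_model, spike_triggered_mean

from conftest import make_pair, make_random_mn, make_random_mxr


class TestEStep:
    def test_single_path_model_gives_unit_transition_counts(self, rng):
        emb = StimulusEmbeddingSpec(window_length=2, channels=1)
        m = build_mn_template(1, emb, spike_rate=0.4)
        pair = make_pair(rng, 4)
        (stats,) = e_step(m, [pair])
        # the only path visits M four times: three internal transitions
        assert np.isclose(stats.transitions.xi_sums[0, 0], 3.0, atol=1e-10)
        np.testing.assert_allclose(stats.transitions.start_occupancy, [1.0])
        np.testing.assert_allclose(stats.transitions.terminal_occupancy, [1.0])

    def test_flow_conservation(self, rng):
        # expected transitions into a state plus its start occupancy equal
        # its total posterior occupancy (every visit is entered exactly once)
        for _ in range(5):
            m = make_random_mxr(rng)
            pair = make_pair(rng, 3, 3)
            (stats,) = e_step(m, [pair])
            occ = stats.field.gamma.sum(axis=(0, 1))
            into = stats.transitions.xi_sums.sum(axis=0) + stats.transitions.start_occupancy
            np.testing.assert_allclose(into, occ, atol=1e-9)

    def test_total_loglik_is_sum_over_pairs(self, rng):
        m = make_random_mxr(rng)
        pairs = [make_pair(rng, 3), make_pair(rng, 4)]
        stats = e_step(m, pairs)
        from mphmm import forward

        expected = sum(forward(m, p).log_likelihood for p in pairs)
        assert np.isclose(sum(s.log_likelihood for s in stats), expected, atol=1e-10)

    def test_impossible_pair_named(self, rng):
        m = make_random_mxr(rng, r_spike=0.0)
        m.states[0].emission.response_marginal.probs = np.array([1.0, 0.0])
        pair = make_pair(rng, 2, p_spike=1.0)  # spikes cannot be emitted
        with pytest.raises(ValueError, match="pair 0"):
            e_step(m, [pair])


class TestMStep:
    def test_one_iteration_sets_spike_mean_to_spike_triggered_average(self, rng):
        # single M-state, identity covariance: the EM mean update weights
        # every spike bin with posterior 1, giving exactly the mean of the
        # spike-triggered ensemble
        emb = StimulusEmbeddingSpec(window_length=3, channels=1)
        m = build_mn_template(1, emb, spike_rate=0.3)
        pair = make_pair(rng, 200, d=3, p_spike=0.3)
        new = m_step(m, [pair], e_step(m, [pair]))
        sta = pair.stimulus[pair.response > 0].mean(axis=0)
        np.testing.assert_allclose(
            new.states[0].emission.conditional_stimulus[1].means[0], sta, atol=1e-12
        )
        np.testing.assert_allclose(
            new.states[0].emission.conditional_stimulus[1].means[0],
            spike_triggered_mean([pair]),
            rtol=1e-10,
        )

    def test_fully_frozen_model_unchanged(self, rng):
        m = make_random_mxr(rng)
        m.states[0].emission.response_marginal.frozen = True
        m.states[0].emission.conditional_stimulus[1].mean_mode = "fixed_value"
        cfg = EMConfig(freeze_transitions=True, freeze_initial=True, freeze_final=True)
        pair = make_pair(rng, 5)
        new = m_step(m, [pair], e_step(m, [pair]), cfg)
        np.testing.assert_array_equal(new.transitions, m.transitions)
        np.testing.assert_array_equal(new.initial, m.initial)
        np.testing.assert_array_equal(new.final, m.final)
        np.testing.assert_array_equal(
            new.states[0].emission.conditional_stimulus[1].means,
            m.states[0].emission.conditional_stimulus[1].means,
        )
        np.testing.assert_array_equal(
            new.states[2].emission.probs, m.states[2].emission.probs
        )

    def test_free_gaussian_single_path_matches_weighted_moments(self, rng):
        # single M-state with free mean AND free covariance: posterior is 1
        # along the only path, so the update equals the plain sample moments
        # of the consumed stimuli (split by response symbol)
        emb = StimulusEmbeddingSpec(window_length=2, channels=1)
        m = build_mn_template(1, emb, spike_rate=0.5)
        for g in m.states[0].emission.conditional_stimulus:
            g.mean_mode = "free"
            g.covariance_mode = "free"
        pair = make_pair(rng, 300, p_spike=0.5)
        new = m_step(m, [pair], e_step(m, [pair]))
        for v in (0, 1):
            sel = pair.stimulus[pair.response == v]
            g = new.states[0].emission.conditional_stimulus[v]
            np.testing.assert_allclose(g.means[0], sel.mean(axis=0), atol=1e-10)
            np.testing.assert_allclose(
                g.covariances[0], np.cov(sel.T, bias=True), atol=1e-8
            )

    def test_updated_distributions_renormalize_exactly(self, rng):
        m = make_random_mxr(rng)
        pairs = [make_pair(rng, 6) for _ in range(2)]
        new = m_step(m, pairs, e_step(m, pairs))
        rows = new.transitions.sum(axis=1) + new.final
        np.testing.assert_allclose(rows, 1.0, atol=1e-12)
        assert np.isclose(new.initial.sum(), 1.0, atol=1e-12)
        assert np.isclose(new.states[0].emission.response_marginal.probs.sum(), 1.0, atol=1e-12)

    def test_constraint_flags_hold_bit_exactly(self, rng):
        m = make_random_mxr(rng)  # identity covariances, fixed zero means
        pairs = [make_pair(rng, 8)]
        new = m_step(m, pairs, e_step(m, pairs))
        d = m.dim
        for st in new.states:
            if st.kind == "X":
                assert np.array_equal(st.emission.covariances[0], np.eye(d))
                assert np.array_equal(st.emission.means[0], np.zeros(d))
            elif st.kind == "M":
                for g in st.emission.conditional_stimulus:
                    assert np.array_equal(g.covariances[0], np.eye(d))
                assert np.array_equal(
                    st.emission.conditional_stimulus[0].means[0], np.zeros(d)
                )
            else:
                assert np.array_equal(st.emission.probs, m.states[2].emission.probs)


class TestEMFit:
    def test_shared_covariance_single_state_converges_immediately(self, rng):
        # fixed shared covariance, free mean: the likelihood is maximized by
        # the first M-step, so the fit stops after one parameter update
        emb = StimulusEmbeddingSpec(window_length=2, channels=1)
        m = build_mn_template(1, emb, spike_rate=0.3)
        pair = make_pair(rng, 300, p_spike=0.3)
        _, trace, _ = em_fit(m, [pair], EMConfig(max_iters=20))
        assert len(trace) <= 3
        assert trace[-1] >= trace[0] - 1e-8

    def test_already_converged_model_short_trace(self, rng):
        emb = StimulusEmbeddingSpec(window_length=2, channels=1)
        m = build_mn_template(1, emb, spike_rate=0.3)
        pair = make_pair(rng, 100, p_spike=0.3)
        fitted, _, _ = em_fit(m, [pair], EMConfig(max_iters=20))
        _, trace, _ = em_fit(fitted, [pair], EMConfig(max_iters=20))
        assert len(trace) <= 2

    @pytest.mark.parametrize("arch", ["m", "mxr", "m2"])
    def test_monotone_loglik_across_architectures(self, rng, arch):
        for trial in range(4):
            if arch == "mxr":
                m = make_random_mxr(rng, r_spike=0.0)
            elif arch == "m2":
                m = make_random_mn(rng, n=2)
            else:
                m = make_random_mn(rng, n=1)
            pairs = [make_pair(rng, 40) for _ in range(2)]
            fitted, trace, _ = em_fit(m, pairs, EMConfig(max_iters=12))
            assert np.all(np.diff(trace) > -1e-8)
            assert validate_model(fitted) == []

    def test_best_restart_selected(self, rng):
        m = make_random_mn(rng, n=2)
        pairs = [make_pair(rng, 60) for _ in range(2)]
        _, trace, diag = em_fit(m, pairs, EMConfig(max_iters=10, n_restarts=3, seed=0))
        lls = [r["log_likelihood"] for r in diag["restarts"]]
        assert np.isclose(trace[-1], max(lls))

    def test_invalid_model_rejected(self, rng):
        m = make_random_mxr(rng)
        m.transitions[0, 0] += 0.5
        with pytest.raises(ValueError, match="invalid model"):
            em_fit(m, [make_pair(rng, 4)])


class TestInitialization:
    def test_initialize_model_is_valid_and_uses_spike_statistics(self, rng):
        emb = StimulusEmbeddingSpec(window_length=3, channels=1)
        m = build_mn_template(2, emb, spike_rate=0.01)
        pairs = [make_pair(rng, 100, d=3, p_spike=0.3)]
        init = initialize_model(m, pairs, rng)
        assert validate_model(init) == []
        sta = spike_triggered_mean(pairs)
        for st in init.states:
            got = st.emission.conditional_stimulus[1].means[0]
            assert np.linalg.norm(got - sta) < 1.0  # centered on the STA
        # marginal re-initialized to the empirical rate
        p1 = init.states[0].emission.response_marginal.probs[1]
        rate = np.mean([p.response.mean() for p in pairs])
        assert abs(p1 - rate) < 1e-9

    def test_parameter_recovery_mxr_beats_sta_under_jitter(self, rng):
        # compact recovery check: jittered spikes from a known filter; the
        # EM-fitted aligned RF must be closer (shift-invariant cosine) to the
        # truth than the raw STA
        from mphmm.experiments import run_jitter_experiment

        res = run_jitter_experiment(
            seed=7,
            n_bins=6000,
            sigma2_grid=(4.0,),
            em_iters=25,
            n_restarts=1,
            n_val_seq=1,
        )
        r = res["per_sigma"][0]
        assert r["cos_mph"] > r["cos_sta"]
        assert r["cos_mph"] >= 0.85
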