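"""Alignment-tensor recursions against the brute-force path oracle."""

import numpy as np
import pytest

from mphmm import (
    StimulusEmbeddingSpec,
    StimulusResponsePair,
    alignment_kernel,
    backward,
    build_mn_template,
    enumerate_paths_bruteforce,
    forward,
    forward_backward,
    posteriors,
    viterbi,
)
from mphmm.model import build_mxr_template

from conftest import make_pair, make_random_mn, make_random_mxr


def _single_m_model(d=2, spike_rate=0.4):
    emb = StimulusEmbeddingSpec(window_length=d, channels=1)
    m = build_mn_template(1, emb, spike_rate=spike_rate)
    m.states[0].emission.conditional_stimulus[1].means[0] = np.ones(d)
    return m


class TestForward:
    def test_single_m_state_single_bin_closed_form(self, rng):
        m = _single_m_model()
        pair = make_pair(rng, 1)
        t = forward(m, pair)
        em = m.states[0].emission
        v = pair.response[0]
        e = em.response_marginal.probs[v] * np.exp(
            em.conditional_stimulus[v].log_pdf(pair.stimulus)[0]
        )
        expected = np.log(m.initial[0] * e * m.final[0])
        assert np.isclose(t.log_likelihood, expected, atol=1e-12)

    @pytest.mark.parametrize("trial", range(12))
    def test_loglik_matches_brute_force(self, rng, trial):
        m = make_random_mxr(rng, r_spike=0.3 if trial % 2 else 0.0)
        pair = make_pair(rng, int(rng.integers(1, 4)), int(rng.integers(1, 4)))
        _, total = enumerate_paths_bruteforce(m, pair)
        assert np.isclose(forward(m, pair).log_likelihood, np.log(total), atol=1e-10)

    def test_band_enlargement_beyond_sequence_is_exact(self, rng):
        m = make_random_mxr(rng, W=5)
        pair = make_pair(rng, 5)
        ll = forward(m, pair).log_likelihood
        m.band_width = 50
        assert np.isclose(forward(m, pair).log_likelihood, ll, atol=1e-10)

    def test_band_too_narrow_raises(self, rng):
        m = make_random_mxr(rng, W=2)
        with pytest.raises(ValueError, match="band"):
            forward(m, make_pair(rng, 8, 2))

    def test_m_only_model_rejects_unequal_lengths(self, rng):
        m = _single_m_model()
        m.band_width = 5
        with pytest.raises(ValueError, match="no X-state"):
            forward(m, make_pair(rng, 4, 2))

    def test_log_domain_stability_long_sequence(self, rng):
        # Tx = 10^4 at d = 40: per-bin log densities ~ -50, total ~ -5e5;
        # must remain finite without underflow.
        emb = StimulusEmbeddingSpec(window_length=40, channels=1)
        m = build_mn_template(1, emb, spike_rate=0.05)
        pair = make_pair(rng, 10_000, d=40, p_spike=0.05)
        ll = forward(m, pair).log_likelihood
        assert np.isfinite(ll) and ll < -1e5


class TestBackward:
    def test_terminal_beta_equals_tau(self, rng):
        m = make_random_mxr(rng)
        pair = make_pair(rng, 3)
        t = backward(m, pair)
        for s in range(m.n_states):
            expected = np.log(m.final[s]) if m.final[s] > 0 else -np.inf
            assert np.isclose(t.beta(pair.Tx, pair.Tr, s), expected, atol=1e-12)

    def test_every_symbol_consumed_exactly_once_in_posterior(self, rng):
        # alpha * beta / P is the posterior of consuming up to (i, j) in
        # state s; every path consumes each response symbol exactly once via
        # an R- or M-state, so these posteriors sum to 1 at every j (and
        # symmetrically for the stimulus via X/M states)
        m = make_random_mxr(rng, W=6)
        pair = make_pair(rng, 3)
        t = forward_backward(m, pair)
        kinds = m.kinds
        for j in range(1, pair.Tr + 1):
            tot = 0.0
            for i in range(pair.Tx + 1):
                if abs(i - j) > t.band_width:
                    continue
                for s in range(m.n_states):
                    if kinds[s] == 0:  # X-states do not consume the response
                        continue
                    a, b = t.alpha(i, j, s), t.beta(i, j, s)
                    if np.isfinite(a) and np.isfinite(b):
                        tot += np.exp(a + b - t.log_likelihood)
            assert np.isclose(tot, 1.0, rtol=1e-9)


class TestViterbi:
    def test_single_m_state_unique_path(self, rng):
        m = _single_m_model()
        pair = make_pair(rng, 4)
        path, lp = viterbi(m, pair)
        assert path.kinds == ["M"] * 4
        assert np.isclose(lp, forward(m, pair).log_likelihood, atol=1e-12)

    def test_zero_probability_xr_transitions_force_diagonal(self, rng):
        m = make_random_mxr(rng)
        # zero out all movement into X and R states
        m.transitions[:, 1:] = 0.0
        m.initial = np.array([1.0, 0.0, 0.0])
        m.transitions[:, 0] = 1.0 - m.final
        path, _ = viterbi(m, make_pair(rng, 4))
        assert path.kinds == ["M"] * 4

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_maximum(self, rng, trial):
        m = make_random_mxr(rng)
        pair = make_pair(rng, 3, int(rng.integers(1, 4)))
        paths, _ = enumerate_paths_bruteforce(m, pair)
        best_p = max(p for _, p in paths)
        path, lp = viterbi(m, pair)
        assert np.isclose(np.exp(lp), best_p, rtol=1e-9)
        # the returned path itself must carry maximal probability (distinct
        # argmax paths can tie; the tie-break is deterministic but arbitrary)
        returned = next(prob for q, prob in paths if q.states == path.states)
        assert np.isclose(returned, best_p, rtol=1e-9)


class TestPosteriors:
    def test_single_path_posterior_is_one(self, rng):
        m = _single_m_model()
        pair = make_pair(rng, 3)
        field = posteriors(m, pair)
        for t in range(1, 4):
            assert np.isclose(field.at(t, t, 0), 1.0, atol=1e-12)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_path_mass_fractions(self, rng, trial):
        m = make_random_mxr(rng)
        pair = make_pair(rng, 3, 3)
        paths, total = enumerate_paths_bruteforce(m, pair)
        field = posteriors(m, pair)
        mass: dict = {}
        for p, prob in paths:
            for (i, j), s in zip(p.trajectory[1:], p.states):
                mass[(i, j, s)] = mass.get((i, j, s), 0.0) + prob
        for (i, j, s), v in mass.items():
            assert np.isclose(field.at(i, j, s), v / total, atol=1e-10)
        assert np.all(field.gamma >= -1e-15) and np.all(field.gamma <= 1 + 1e-12)


class TestAlignmentKernel:
    def test_m_only_model_gives_delta_at_zero(self, rng):
        m = _single_m_model()
        pair = make_pair(rng, 5, p_spike=0.8)
        k = alignment_kernel(m, pair)
        assert np.isclose(k.probs[k.lags == 0][0], 1.0)
        assert np.isclose(k.probs.sum(), 1.0, atol=1e-10)

    def test_no_spikes_raises(self, rng):
        m = _single_m_model()
        pair = StimulusResponsePair(rng.normal(size=(4, 2)), np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="kernel undefined"):
            alignment_kernel(m, pair)

    def test_delayed_spike_shifts_mode_to_positive_lag(self, rng):
        # One spike generated at stimulus event t but observed at t+1: its
        # matched stimulus position precedes the spike, so the kernel mode
        # sits at lag = j - i = +1 for a model that strongly prefers the
        # spike-conditioned match.
        d = 2
        emb = StimulusEmbeddingSpec(window_length=d, channels=1)
        m = build_mxr_template(emb, spike_rate=0.2, band_width=2)
        m.states[0].emission.conditional_stimulus[1].means[0] = np.array([4.0, 4.0])
        X = np.zeros((6, d))
        X[2] = [4.0, 4.0]  # the stimulus event the spike belongs to
        r = np.zeros(6, dtype=int)
        r[3] = 1  # observed one bin late
        k = alignment_kernel(m, StimulusResponsePair(X, r))
        assert k.mode_lag() == 1

    def test_kernel_weighted_by_posterior_matches_enumeration(self, rng):
        m = make_random_mxr(rng)
        pair = make_pair(rng, 3, 3, p_spike=0.7)
        paths, total = enumerate_paths_bruteforce(m, pair)
        hist: dict = {}
        for p, prob in paths:
            for (i, j), s, kd in zip(p.trajectory[1:], p.states, p.kinds):
                if kd == "M" and pair.response[j - 1] > 0:
                    hist[j - i] = hist.get(j - i, 0.0) + prob
        tot = sum(hist.values())
        k = alignment_kernel(m, pair)
        for lag, v in hist.items():
            assert np.isclose(k.probs[k.lags == lag][0], v / tot, atol=1e-10)


class TestBruteForce:
    def test_single_m_state_has_one_path(self, rng):
        m = _single_m_model()
        paths, _ = enumerate_paths_bruteforce(m, make_pair(rng, 2))
        assert len(paths) == 1

    def test_path_count_matches_lattice_path_enumeration(self, rng):
        # MXR with one state per kind: state sequence is determined by the
        # step sequence, so path count equals the number of banded monotone
        # lattice paths (0,0)->(2,2) counted independently.
        m = make_random_mxr(rng, W=2, r_spike=0.5)
        paths, _ = enumerate_paths_bruteforce(m, make_pair(rng, 2))

        def count(i, j):
            if abs(i - j) > 2:
                return 0
            if (i, j) == (2, 2):
                return 1
            n = 0
            if i < 2:
                n += count(i + 1, j)
            if j < 2:
                n += count(i, j + 1)
            if i < 2 and j < 2:
                n += count(i + 1, j + 1)
            return n

        assert len(paths) == count(0, 0)

    def test_cap_enforced(self, rng):
        m = make_random_mxr(rng, W=4)
        with pytest.raises(RuntimeError, match="cap"):
            enumerate_paths_bruteforce(m, make_pair(rng, 4), max_paths=2)


class TestComplexity:
    def test_runtime_scales_near_linearly_in_sequence_length(self, rng):
        import time

        emb = StimulusEmbeddingSpec(window_length=4, channels=1)
        m = build_mxr_template(emb, band_width=6)

        def timed(T):
            pair = make_pair(rng, T, d=4, p_spike=0.05)
            t0 = time.perf_counter()
            forward_backward(m, pair)
            return time.perf_counter() - t0

        timed(500)  # warm-up (JIT compile)
        t1 = min(timed(4000) for _ in range(3))
        t2 = min(timed(16000) for _ in range(3))
        # 4x the length: allow up to ~quadratic headroom but require clearly
        # sub-quadratic behavior (exponent < 1.5 => ratio < 8)
        assert t2 / t1 < 8.0, f"scaling ratio {t2 / t1:.1f} for 4x length"
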