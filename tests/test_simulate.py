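"""Simulators, spike-triggered baselines, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mphmm.baselines import (
    cc_upper_bound,
    cosine_similarity,
    evaluate_cc,
    lnp_from_mmph,
    rc_fit,
    sta_fit,
    stc_fit,
)
from mphmm.model import StimulusEmbeddingSpec, StimulusResponsePair, embed_stimulus
from mphmm.simulate import (
    LNPSpec,
    SwitchSpec,
    apply_jitter,
    calibrate_lnp,
    correlated_stimulus,
    discretized_lognormal_kernel,
    lnp_simulate,
    switching_lnp_simulate,
    white_noise_stimulus,
)


class TestStimuli:
    def test_white_noise_reproducible_and_standardized(self):
        a = white_noise_stimulus(3, 5000, seed=11)
        b = white_noise_stimulus(3, 5000, seed=11)
        np.testing.assert_array_equal(a, b)
        assert abs(a.mean()) < 3 / np.sqrt(a.size)
        spec = StimulusEmbeddingSpec(window_length=4, channels=3)
        X = embed_stimulus(a, spec)
        C = np.cov(X[4:].T)
        assert np.abs(C - np.eye(12)).max() < 0.1

    def test_correlated_stimulus_ar1_autocorrelation(self):
        Z = correlated_stimulus(1, 60_000, ar_coeff=0.9, channel_scale=0.0, seed=2)
        z = Z[0] - Z[0].mean()
        r1 = np.dot(z[:-1], z[1:]) / np.dot(z, z)
        assert abs(r1 - 0.9) < 0.02

    def test_zero_correlation_reduces_to_white(self):
        Z = correlated_stimulus(2, 30_000, ar_coeff=0.0, channel_scale=0.0, seed=3)
        assert abs(np.var(Z) - 1.0) < 0.05
        r1 = np.corrcoef(Z[0, :-1], Z[0, 1:])[0, 1]
        assert abs(r1) < 0.02

    def test_invalid_ar_coefficient(self):
        with pytest.raises(ValueError):
            correlated_stimulus(1, 10, ar_coeff=1.5)


class TestLNP:
    def test_degenerate_rates(self):
        X = np.random.default_rng(0).normal(size=(100, 3))
        zero = LNPSpec(filter=np.zeros(3), slope=1.0, offset=-100.0)
        np.testing.assert_array_equal(lnp_simulate(zero, X, seed=0), 0)
        one = LNPSpec(filter=np.zeros(3), slope=1.0, offset=100.0)
        np.testing.assert_array_equal(lnp_simulate(one, X, seed=0), 1)

    def test_calibration_hits_target_rate(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100_000, 5))
        w = rng.normal(size=5)
        spec = calibrate_lnp(w, X, slope=4.0, target_rate=0.015)
        spikes = lnp_simulate(spec, X, seed=5)
        assert abs(spikes.mean() - 0.015) / 0.015 < 0.1


class TestJitterKernel:
    def test_zero_variance_is_delta(self):
        jit = discretized_lognormal_kernel(0.0)
        assert jit.probs[jit.lags == 0][0] == 1.0

    @settings(derandomize=True, max_examples=20)
    @given(sigma2=st.floats(0.25, 12.0))
    def test_normalized_near_zero_mean_positive_skew(self, sigma2):
        jit = discretized_lognormal_kernel(sigma2, support=np.arange(-40, 200))
        assert np.isclose(jit.probs.sum(), 1.0, atol=1e-12)
        assert abs(jit.mean()) <= 0.75  # within discretization error
        assert jit.skewness() > 0.0

    def test_skewness_grows_with_variance(self):
        s1 = discretized_lognormal_kernel(1.0, np.arange(-30, 120)).skewness()
        s2 = discretized_lognormal_kernel(8.0, np.arange(-30, 120)).skewness()
        assert s2 > s1


class TestApplyJitter:
    def test_delta_kernel_is_identity(self, rng):
        spikes = (rng.random(500) < 0.1).astype(int)
        jit = discretized_lognormal_kernel(0.0)
        np.testing.assert_array_equal(apply_jitter(spikes, jit, seed=0), spikes)

    def test_spike_count_preserved_up_to_clipping(self, rng):
        spikes = (rng.random(2000) < 0.02).astype(int)
        jit = discretized_lognormal_kernel(2.0)
        out = apply_jitter(spikes, jit, seed=1)
        assert out.sum() <= spikes.sum()
        assert out.sum() >= spikes.sum() - 8  # rare collisions / edge losses

    def test_cross_correlogram_recovers_pmf(self):
        rng = np.random.default_rng(6)
        T = 400_000
        spikes = np.zeros(T, dtype=int)
        # sparse spikes so jittered copies rarely collide
        spikes[rng.choice(T, size=10_000, replace=False)] = 1
        jit = discretized_lognormal_kernel(3.0)
        out = apply_jitter(spikes, jit, seed=7)
        times = np.flatnonzero(spikes)
        counts = np.array(
            [np.sum(out[np.clip(times + lag, 0, T - 1)]) for lag in jit.lags],
            dtype=float,
        )
        # subtract the chance coincidence level of unrelated spikes
        counts -= len(times) * out.sum() / T
        counts = np.clip(counts, 0.0, None)
        xcorr = counts / counts.sum()
        assert 0.5 * np.abs(xcorr - jit.probs).sum() < 0.05


class TestSwitching:
    def test_stay_probability_one_keeps_single_model(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(2000, 3))
        spec = SwitchSpec(
            models=[
                LNPSpec(filter=np.ones(3), offset=-2.0),
                LNPSpec(filter=-np.ones(3), offset=-2.0),
            ],
            stay_prob=1.0,
        )
        _, states = switching_lnp_simulate(spec, X, seed=9)
        assert len(np.unique(states)) == 1

    def test_symmetric_switching_occupancy_balanced(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60_000, 2))
        spec = SwitchSpec(
            models=[LNPSpec(filter=np.ones(2)), LNPSpec(filter=-np.ones(2))],
            stay_prob=0.9,
        )
        _, states = switching_lnp_simulate(spec, X, seed=11)
        occ = np.bincount(states, minlength=2) / len(states)
        assert abs(occ[0] - 0.5) < 0.05

    def test_identical_models_match_single_lnp_statistics(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50_000, 3))
        lnp = LNPSpec(filter=np.array([1.0, -1.0, 0.5]), offset=-2.0)
        spec = SwitchSpec(models=[lnp, lnp], stay_prob=0.5)
        spikes, _ = switching_lnp_simulate(spec, X, seed=13)
        single = lnp_simulate(lnp, X, seed=14)
        assert abs(spikes.mean() - single.mean()) < 0.01


class TestSpikeTriggered:
    def _linear_gaussian_pairs(self, rng, T=40_000, d=6, white=True):
        if white:
            X = rng.normal(size=(T, d))
        else:
            A = rng.normal(size=(d, d)) / np.sqrt(d)
            X = rng.normal(size=(T, d)) @ (np.eye(d) + 0.7 * A)
        w = rng.normal(size=d)
        w /= np.linalg.norm(w)
        p = 1 / (1 + np.exp(-(4 * X @ w - 3)))
        r = (rng.random(T) < p).astype(int)
        return [StimulusResponsePair(X, r)], w

    def test_rc_equals_sta_on_white_stimuli(self, rng):
        pairs, _ = self._linear_gaussian_pairs(rng, T=5000)
        sta = sta_fit(pairs)
        rc = rc_fit(pairs, cov=np.eye(6))
        np.testing.assert_allclose(rc, sta, atol=1e-12)

    def test_rc_recovers_filter_direction_on_correlated_stimuli(self, rng):
        pairs, w = self._linear_gaussian_pairs(rng, white=False)
        rc = rc_fit(pairs)
        assert cosine_similarity(rc, w) > 0.95

    def test_regularization_handles_degenerate_channel(self, rng):
        pairs, _ = self._linear_gaussian_pairs(rng, T=3000)
        pairs[0].stimulus[:, 0] = 0.0  # zero-variance dimension
        rc = rc_fit(pairs, lam=0.1)
        assert np.all(np.isfinite(rc))

    def test_no_spikes_raises(self, rng):
        pair = StimulusResponsePair(rng.normal(size=(50, 3)), np.zeros(50, dtype=int))
        with pytest.raises(ValueError, match="no spikes"):
            sta_fit([pair])

    def test_stc_filters_orthonormal(self, rng):
        pairs, _ = self._linear_gaussian_pairs(rng, T=8000)
        F, _ = stc_fit(pairs, n_filters=3)
        np.testing.assert_allclose(F @ F.T, np.eye(3), atol=1e-10)

    def test_symmetric_pooling_defeats_sta_but_not_stc(self, rng):
        # spikes triggered by |w . x|: STA cancels, the top STC filter
        # aligns with +-w
        T, d = 60_000, 8
        X = rng.normal(size=(T, d))
        w = np.zeros(d)
        w[2] = 1.0
        p = 1 / (1 + np.exp(-(6 * np.abs(X @ w) - 10)))
        r = (rng.random(T) < p).astype(int)
        pairs = [StimulusResponsePair(X, r)]
        sta = sta_fit(pairs)
        F, _ = stc_fit(pairs, n_filters=1)
        assert np.linalg.norm(sta) < 0.2
        assert abs(cosine_similarity(F[0], w)) > 0.95

    def test_gaussian_null_spectrum_near_zero(self, rng):
        # spikes independent of the stimulus: the STC difference matrix has
        # eigenvalues concentrated near zero
        X = rng.normal(size=(40_000, 5))
        r = (rng.random(40_000) < 0.05).astype(int)
        _, eigs = stc_fit([StimulusResponsePair(X, r)], n_filters=5)
        assert np.abs(eigs).max() < 0.15


class TestMetrics:
    def test_identical_series_cc_one(self):
        x = np.random.default_rng(1).random(500)
        assert np.isclose(evaluate_cc(x, x), 1.0)

    def test_independent_noise_cc_near_zero(self):
        r = np.random.default_rng(2)
        assert abs(evaluate_cc(r.random(20_000), r.random(20_000))) < 0.05

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(evaluate_cc(np.ones(50), np.random.rand(50)))

    def test_upper_bound_decreases_with_jitter_variance(self):
        rng = np.random.default_rng(3)
        spikes = (rng.random(8000) < 0.05).astype(int)
        ubs = [
            cc_upper_bound(spikes, discretized_lognormal_kernel(s2), n_samples=6, seed=4)
            for s2 in (0.5, 3.0, 9.0)
        ]
        assert ubs[0] > ubs[1] > ubs[2]

    def test_cosine_basic_and_shift_invariant(self):
        a = np.array([1.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 0.0])
        assert cosine_similarity(a, a) == 1.0
        assert cosine_similarity(a, b) == 0.0
        # b is a shifted by one window bin
        assert np.isclose(cosine_similarity(a, b, shift_invariant=True, channels=1), 1.0)
        with pytest.raises(ValueError):
            cosine_similarity(a, np.zeros(4))

    def test_shift_invariant_two_channel_shift(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(2, 6))
        shifted = np.zeros_like(base)
        shifted[:, 2:] = base[:, :4]
        c = cosine_similarity(
            base.ravel(), shifted.ravel(), shift_invariant=True, channels=2
        )
        assert c > 0.8  # edge truncation keeps it below 1 but high


class TestLNPBridge:
    def test_bridge_rejects_multi_state_models(self, rng):
        from conftest import make_random_mn

        with pytest.raises(ValueError, match="one M-state"):
            lnp_from_mmph(make_random_mn(rng, n=2))

    def test_bridge_filter_is_whitened_mean_difference(self, rng):
        from mphmm.model import build_mn_template

        d = 3
        emb = StimulusEmbeddingSpec(window_length=d, channels=1)
        A = rng.normal(size=(d, d))
        Sig = A @ A.T + d * np.eye(d)
        m = build_mn_template(1, emb, spike_rate=0.2, cov_mode="fixed_shared", data_cov=Sig)
        mu1 = rng.normal(size=d)
        m.states[0].emission.conditional_stimulus[1].means[0] = mu1
        lnp = lnp_from_mmph(m)
        np.testing.assert_allclose(lnp.filter, np.linalg.solve(Sig, mu1), atol=1e-12)
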