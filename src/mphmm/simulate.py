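"""Synthetic-data generators for the reference experiments.

White-noise and correlated Gaussian stimuli, linear-nonlinear Bernoulli
spiking (an LNP cascade at one spike per bin), i.i.d. spike-time jitter
drawn from a discretized log-normal kernel, and Markov-switching two-filter
responses.  Every generator takes an explicit seed (or Generator) and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "LNPSpec",
    "JitterSpec",
    "SwitchSpec",
    "white_noise_stimulus",
    "correlated_stimulus",
    "calibrate_lnp",
    "lnp_simulate",
    "discretized_lognormal_kernel",
    "apply_jitter",
    "switching_lnp_simulate",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


@dataclass
class LNPSpec:
    """Linear filter + sigmoid nonlinearity + Bernoulli spiking rule.

    Per-bin spike probability is ``sigmoid(slope * (w . x) + offset)``;
    ``slope`` controls the steepness of the nonlinearity, ``offset`` the
    operating point (and hence the mean rate).
    """

    filter: np.ndarray
    slope: float = 1.0
    offset: float = 0.0
    target_rate: float | None = None  # spikes/bin the offset was calibrated to

    def __post_init__(self) -> None:
        self.filter = np.asarray(self.filter, dtype=float)
        if not np.all(np.isfinite(self.filter)):
            raise ValueError("filter must be finite")

    def rate(self, X: np.ndarray) -> np.ndarray:
        """Spike probability per bin for embedded stimuli ``X`` (T, d)."""
        p = sigmoid(self.slope * (np.atleast_2d(X) @ self.filter) + self.offset)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("nonlinearity produced probabilities outside [0, 1]")
        return p


@dataclass
class JitterSpec:
    """Discretized zero-mean jitter pmf over integer lags (i.i.d. per spike)."""

    lags: np.ndarray
    probs: np.ndarray
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)

    def mean(self) -> float:
        return float(np.dot(self.lags, self.probs))

    def variance(self) -> float:
        m = self.mean()
        return float(np.dot((self.lags - m) ** 2, self.probs))

    def skewness(self) -> float:
        m, v = self.mean(), self.variance()
        if v <= 0:
            return 0.0
        return float(np.dot((self.lags - m) ** 3, self.probs) / v**1.5)


@dataclass
class SwitchSpec:
    """Two (or more) LNP models with a Markov switching process.

    ``stay_prob`` builds a symmetric transition matrix when ``switching`` is
    not given explicitly.
    """

    models: list[LNPSpec]
    stay_prob: float = 0.98
    switching: np.ndarray | None = None

    def transition_matrix(self) -> np.ndarray:
        n = len(self.models)
        if self.switching is not None:
            P = np.asarray(self.switching, dtype=float)
            if P.shape != (n, n) or not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError("switching matrix must be row-stochastic (n x n)")
            return P
        off = (1.0 - self.stay_prob) / max(n - 1, 1)
        P = np.full((n, n), off)
        np.fill_diagonal(P, self.stay_prob)
        return P


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


def white_noise_stimulus(channels: int, T: int, seed=None) -> np.ndarray:
    """I.i.d. standard-normal stimulus matrix, shape ``(channels, T)``."""
    return _rng(seed).normal(size=(channels, T))


def correlated_stimulus(
    channels: int,
    T: int,
    ar_coeff: float = 0.9,
    channel_scale: float = 2.0,
    seed=None,
) -> np.ndarray:
    """Stationary correlated Gaussian stimulus (natural-stimulus stand-in).

    Temporal correlation is AR(1) with coefficient ``ar_coeff``; channels are
    mixed through a squared-exponential kernel with length scale
    ``channel_scale``.  Marginals are standardized to unit variance.  With
    ``ar_coeff = 0`` and ``channel_scale = 0`` this reduces to white noise.
    """
    if not -1.0 < ar_coeff < 1.0:
        raise ValueError("ar_coeff must lie in (-1, 1)")
    rng = _rng(seed)
    Z = rng.normal(size=(channels, T))
    if channel_scale > 0:
        idx = np.arange(channels)
        K = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / channel_scale) ** 2)
        K += 1e-10 * np.eye(channels)
        w = np.linalg.eigvalsh(K)
        if w.min() <= 0:
            raise ValueError("channel kernel not positive definite")
        L = np.linalg.cholesky(K)
        Z = L @ Z
    if ar_coeff != 0.0:
        Z = signal.lfilter([1.0], [1.0, -ar_coeff], Z, axis=1)
        Z *= np.sqrt(1.0 - ar_coeff**2)  # unit stationary variance
    return Z


# ---------------------------------------------------------------------------
# LNP spiking
# ---------------------------------------------------------------------------


def calibrate_lnp(
    filter: np.ndarray,
    X: np.ndarray,
    slope: float = 1.0,
    target_rate: float = 0.015,
) -> LNPSpec:
    """Solve the sigmoid offset so the mean rate on ``X`` hits ``target_rate``.

    Bisection on the offset at fixed slope; monotonicity of the sigmoid makes
    the root unique.
    """
    filter = np.asarray(filter, dtype=float)
    proj = slope * (np.atleast_2d(X) @ filter)

    def mean_rate(c: float) -> float:
        return float(np.mean(sigmoid(proj + c))) - target_rate

    lo, hi = -60.0, 60.0
    c = optimize.brentq(mean_rate, lo, hi, xtol=1e-12)
    return LNPSpec(filter=filter, slope=slope, offset=float(c), target_rate=target_rate)


def lnp_simulate(spec: LNPSpec, X: np.ndarray, seed=None) -> np.ndarray:
    """Sample a binary spike train: Bernoulli per bin at rate ``spec.rate``."""
    p = spec.rate(X)
    return (_rng(seed).random(len(p)) < p).astype(np.int64)


# ---------------------------------------------------------------------------
# jitter
# ---------------------------------------------------------------------------


def discretized_lognormal_kernel(
    sigma2: float, support: np.ndarray | None = None
) -> JitterSpec:
    """Zero-mean discretized log-normal jitter pmf with variance ~ ``sigma2``.

    The log-normal density (scale 1, shape solved so the continuous variance
    equals ``sigma2``) is sampled at integer spacing with its continuous
    mean placed at lag 0, then renormalized.  As the variance grows the pmf
    becomes more asymmetric with a heavy right tail.  ``sigma2 <= 0`` gives
    a delta at lag 0.
    """
    if support is None:
        w = max(4, int(np.ceil(4 * np.sqrt(max(sigma2, 0.25)))))
        support = np.arange(-w, w + 1)
    support = np.asarray(support, dtype=np.int64)
    probs = np.zeros(len(support), dtype=float)
    if sigma2 <= 0:
        probs[support == 0] = 1.0
        return JitterSpec(support, probs, 0.0)

    def var_of_shape(s: float) -> float:
        return (np.exp(s**2) - 1.0) * np.exp(s**2)

    s = optimize.brentq(lambda s: var_of_shape(s) - sigma2, 1e-9, 4.0)
    m = float(np.exp(s**2 / 2.0))  # continuous mean, placed at lag 0
    x = support + m
    probs = np.where(x > 0, stats.lognorm.pdf(np.maximum(x, 1e-300), s), 0.0)
    tot = probs.sum()
    if tot <= 0:
        raise ValueError("support does not cover the jitter distribution")
    return JitterSpec(support, probs / tot, float(sigma2))


def apply_jitter(spikes: np.ndarray, jitter: JitterSpec, seed=None) -> np.ndarray:
    """Move each spike by an independent draw from the jitter pmf.

    Spikes shifted outside the sequence are dropped; multiple spikes landing
    in one bin collapse to a single spike (binary trains).
    """
    spikes = np.asarray(spikes)
    rng = _rng(seed)
    T = len(spikes)
    times = np.flatnonzero(spikes > 0)
    shifts = rng.choice(jitter.lags, size=len(times), p=jitter.probs)
    new_times = times + shifts
    new_times = new_times[(new_times >= 0) & (new_times < T)]
    out = np.zeros(T, dtype=np.int64)
    out[new_times] = 1
    return out


# ---------------------------------------------------------------------------
# switching responses
# ---------------------------------------------------------------------------


def switching_lnp_simulate(
    spec: SwitchSpec, X: np.ndarray, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Spikes from a Markov-switched set of LNP models.

    Returns ``(spikes, states)`` where ``states[t]`` indexes the active
    model at bin ``t`` (the hidden switching sequence starts from the
    uniform distribution).
    """
    rng = _rng(seed)
    P = spec.transition_matrix()
    n = len(spec.models)
    T = np.atleast_2d(X).shape[0]
    states = np.zeros(T, dtype=np.int64)
    states[0] = rng.integers(n)
    u = rng.random(T)
    cum = np.cumsum(P, axis=1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    rates = np.stack([m.rate(X) for m in spec.models], axis=1)  # (T, n)
    p = rates[np.arange(T), states]
    spikes = (rng.random(T) < p).astype(np.int64)
    return spikes, states
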