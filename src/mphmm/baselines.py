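"""Reference estimators and evaluation metrics.

Spike-triggered average (STA), reverse correlation (covariance-corrected
STA / linear regression), spike-triggered covariance (STC), the bridge
between the single-M-state Gaussian model and an LNP cascade, rate
correlation coefficients with a sampling-based upper bound, and filter
cosine similarity.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .model import MPHModel, StimulusResponsePair, regularize_covariance
from .simulate import JitterSpec, LNPSpec, apply_jitter

__all__ = [
    "lnp_from_mmph",
    "sta_fit",
    "rc_fit",
    "stc_fit",
    "histogram_rate_model",
    "evaluate_cc",
    "cc_upper_bound",
    "cosine_similarity",
]


# ---------------------------------------------------------------------------
# LNP-equivalence bridge
# ---------------------------------------------------------------------------


def lnp_from_mmph(model: MPHModel) -> LNPSpec:
    """Closed-form LNP equivalent of a single-M-state shared-covariance MPH.

    For a matching state with spike prior ``p1``, conditional Gaussian means
    ``mu0`` (no spike) and ``mu1`` (spike) and shared covariance ``Sigma``,
    the posterior spike probability is ``sigmoid(w . x + c)`` with::

        w = Sigma^{-1} (mu1 - mu0)
        c = log(p1 / p0) - (mu1' Sigma^{-1} mu1 - mu0' Sigma^{-1} mu0) / 2

    i.e. a one-dimensional LNP model whose filter is the reverse-correlation
    (whitened spike-triggered average) solution.
    """
    m_states = [st for st in model.states if st.kind == "M"]
    if len(m_states) != 1 or any(st.kind != "M" for st in model.states):
        raise ValueError("LNP bridge requires a model with exactly one M-state")
    em = m_states[0].emission
    if em.n_symbols != 2:
        raise ValueError("LNP bridge requires a binary response")
    g0, g1 = em.conditional_stimulus
    if g0.n_components != 1 or g1.n_components != 1:
        raise ValueError("LNP bridge requires single-Gaussian conditionals")
    if not np.allclose(g0.covariances[0], g1.covariances[0], atol=1e-12):
        raise ValueError("LNP bridge requires a shared covariance matrix")
    Sigma = g0.covariances[0]
    mu0, mu1 = g0.means[0], g1.means[0]
    p0, p1 = em.response_marginal.probs
    if p0 <= 0 or p1 <= 0:
        raise ValueError("spike marginal must be strictly inside (0, 1)")
    w = np.linalg.solve(Sigma, mu1 - mu0)
    c = float(
        np.log(p1 / p0)
        - 0.5 * (mu1 @ np.linalg.solve(Sigma, mu1) - mu0 @ np.linalg.solve(Sigma, mu0))
    )
    return LNPSpec(filter=w, slope=1.0, offset=c)


# ---------------------------------------------------------------------------
# spike-triggered estimators
# ---------------------------------------------------------------------------


def _stack_pairs(pairs: list[StimulusResponsePair]) -> tuple[np.ndarray, np.ndarray]:
    Xs, rs = [], []
    for pair in pairs:
        T = min(pair.Tx, pair.Tr)
        Xs.append(pair.stimulus[:T])
        rs.append(pair.response[:T])
    return np.vstack(Xs), np.concatenate(rs)


def sta_fit(pairs: list[StimulusResponsePair]) -> np.ndarray:
    """Spike-triggered average: mean spike-bin stimulus minus ensemble mean."""
    X, r = _stack_pairs(pairs)
    spk = r > 0
    if not spk.any():
        raise ValueError("no spikes: STA undefined")
    return X[spk].mean(axis=0) - X.mean(axis=0)


def rc_fit(
    pairs: list[StimulusResponsePair],
    lam: float = 0.0,
    cov: np.ndarray | None = None,
) -> np.ndarray:
    """Reverse correlation: covariance-corrected STA.

    Solves ``C w = sta`` where ``C`` is the (optionally shrinkage-
    regularized) stimulus covariance; with white stimuli this reduces to the
    STA.  ``lam > 0`` applies trace-preserving shrinkage toward the scaled
    identity, keeping the solve well conditioned for rank-deficient
    ensembles.
    """
    X, _ = _stack_pairs(pairs)
    sta = sta_fit(pairs)
    if cov is None:
        cov = np.cov(X.T, bias=True)
        cov = np.atleast_2d(cov)
    if lam > 0:
        cov = regularize_covariance(cov, lam)
    return np.linalg.solve(cov, sta)


def stc_fit(
    pairs: list[StimulusResponsePair], n_filters: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-triggered covariance filters.

    Eigenvectors of the difference between the spike-triggered and the full
    stimulus covariance, ranked by eigenvalue magnitude; the returned
    ``(n_filters, d)`` filters are orthonormal.  Also returns the ranked
    eigenvalues.
    """
    X, r = _stack_pairs(pairs)
    spk = r > 0
    if not spk.any():
        raise ValueError("no spikes: STC undefined")
    if spk.sum() < X.shape[1]:
        warnings.warn(
            f"only {int(spk.sum())} spikes for {X.shape[1]} dimensions; "
            "STC estimate will be noisy"
        )
    C_all = np.atleast_2d(np.cov(X.T, bias=True))
    C_spk = np.atleast_2d(np.cov(X[spk].T, bias=True))
    w, U = np.linalg.eigh(C_spk - C_all)
    order = np.argsort(-np.abs(w))[:n_filters]
    return U[:, order].T.copy(), w[order]


def histogram_rate_model(
    filters: np.ndarray,
    X_train: np.ndarray,
    r_train: np.ndarray,
    n_bins: int = 8,
):
    """Subspace-histogram rate predictor for a set of linear filters.

    Projects stimuli on the filters, bins the training projections per
    dimension at equal quantile-free linear spacing, and stores the mean
    spike rate per cell; prediction looks the rate up (empty cells fall
    back to the global mean rate).  This is the standard nonparametric
    nonlinearity estimate used to turn STA/STC filters into rate models.
    """
    filters = np.atleast_2d(np.asarray(filters, dtype=float))
    D = filters.shape[0]
    P = X_train @ filters.T  # (T, D)
    lo = P.min(axis=0)
    hi = P.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    edges = [np.linspace(lo[k], lo[k] + span[k], n_bins + 1) for k in range(D)]
    shape = (n_bins,) * D
    num = np.zeros(shape)
    den = np.zeros(shape)
    idx = tuple(
        np.clip(np.digitize(P[:, k], edges[k][1:-1]), 0, n_bins - 1) for k in range(D)
    )
    np.add.at(num, idx, r_train > 0)
    np.add.at(den, idx, 1.0)
    global_rate = float(np.mean(r_train > 0))
    rate = np.where(den > 0, num / np.maximum(den, 1.0), global_rate)

    def predict(X: np.ndarray) -> np.ndarray:
        Q = np.atleast_2d(X) @ filters.T
        jdx = tuple(
            np.clip(np.digitize(Q[:, k], edges[k][1:-1]), 0, n_bins - 1)
            for k in range(D)
        )
        return rate[jdx]

    return predict


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def evaluate_cc(
    predicted: np.ndarray,
    reference: np.ndarray,
    smooth_width: float = 2.0,
) -> float:
    """Pearson correlation between Gaussian-smoothed rate series.

    Both series are smoothed with the same kernel (sigma ``smooth_width``
    bins) before correlating — the comparison used for response-prediction
    quality.  Returns NaN (with a warning) if either smoothed series has
    zero variance.
    """
    a = gaussian_filter1d(np.asarray(predicted, dtype=float), smooth_width)
    b = gaussian_filter1d(np.asarray(reference, dtype=float), smooth_width)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance series: correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cc_upper_bound(
    spikes: np.ndarray,
    jitter: JitterSpec,
    n_samples: int = 10,
    seed=None,
    smooth_width: float = 2.0,
) -> float:
    """Attainable-CC estimate under the jitter process.

    Independently re-jitters the ideal spike train ``n_samples`` times and
    averages the pairwise CCs between the smoothed jittered rates: no
    predictor conditioned on the stimulus alone can reliably exceed the
    agreement between two fresh draws of the jitter noise.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trains = [apply_jitter(spikes, jitter, rng) for _ in range(n_samples)]
    ccs = []
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            ccs.append(evaluate_cc(trains[i], trains[j], smooth_width))
    return float(np.nanmean(ccs))


def cosine_similarity(
    filter_a: np.ndarray,
    filter_b: np.ndarray,
    shift_invariant: bool = False,
    channels: int = 1,
) -> float:
    """Cosine of the angle between two filters.

    With ``shift_invariant`` the second filter is circularly shifted along
    its within-window time axis (requires the ``channels`` used by the
    embedding) with zero fill, and the maximum cosine over shifts is
    returned — discounting pure latency offsets between estimates.
    """
    a = np.asarray(filter_a, dtype=float).ravel()
    b = np.asarray(filter_b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for zero filters")
    if not shift_invariant:
        return float(a @ b / (na * nb))
    if len(a) % channels:
        raise ValueError("filter length not divisible by channels")
    w = len(a) // channels
    B = b.reshape(channels, w)
    best = -1.0
    for shift in range(-(w - 1), w):
        Bs = np.zeros_like(B)
        if shift >= 0:
            Bs[:, shift:] = B[:, : w - shift]
        else:
            Bs[:, :shift] = B[:, -shift:]
        nb_s = np.linalg.norm(Bs)
        if nb_s == 0:
            continue
        best = max(best, float(a @ Bs.ravel() / (na * nb_s)))
    return best
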