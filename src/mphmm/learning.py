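"""EM parameter estimation for MPHs.

The E-step runs the banded forward-backward recursions per
stimulus-response pair and collects posterior state occupancies plus
expected transition counts; the M-step re-normalizes those sufficient
statistics into new transition, initial, final, discrete-emission, and
Gaussian-mixture parameters, honoring the constraint flags on each
emission.  Statistics are summed over all pairs before normalization, so a
fit over many short sequences maximizes the total data likelihood.

Per-state termination follows the convention ``sum_s' a(s,s') + tau(s) = 1``;
the final probabilities are re-estimated from terminal occupancies,
symmetric to the initial-probability update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _dp
from .alignment import PosteriorField, _band_symbols, _prep
from .model import (
    GaussianMixtureEmission,
    MPHModel,
    StimulusResponsePair,
    validate_model,
)

__all__ = [
    "EMConfig",
    "TransitionPosteriors",
    "PairStatistics",
    "e_step",
    "m_step",
    "em_fit",
    "initialize_model",
    "spike_triggered_mean",
]


@dataclass
class EMConfig:
    """Settings for :func:`em_fit`.

    ``cov_eigenvalue_floor`` is relative to the mean diagonal of each freshly
    estimated free covariance and guards against degenerate components.
    """

    max_iters: int = 200
    loglik_rel_tol: float = 1e-6
    n_restarts: int = 1
    seed: int | None = None
    cov_eigenvalue_floor: float = 1e-6
    freeze_transitions: bool = False
    freeze_initial: bool = False
    freeze_final: bool = False
    freeze_emissions: bool = False
    init_transition_concentration: float = 20.0
    init_mean_noise: float = 0.1

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.loglik_rel_tol <= 0:
            raise ValueError("loglik_rel_tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class TransitionPosteriors:
    """Expected transition counts and boundary occupancies for one pair."""

    xi_sums: np.ndarray  # (N, N) expected transitions s -> s'
    start_occupancy: np.ndarray  # (N,) P(first state = s)
    terminal_occupancy: np.ndarray  # (N,) P(last state = s)


@dataclass
class PairStatistics:
    """E-step output for one stimulus-response pair."""

    field: PosteriorField
    transitions: TransitionPosteriors
    log_likelihood: float


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def e_step(model: MPHModel, pairs: list[StimulusResponsePair]) -> list[PairStatistics]:
    """Forward-backward statistics for every pair under the current model."""
    out = []
    for idx, pair in enumerate(pairs):
        (kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, W, lagmin, lagmax) = _prep(
            model, pair
        )
        alpha, loglik = _dp.forward_kernel(
            kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, pair.Tx, pair.Tr, W,
            lagmin, lagmax,
        )
        if not np.isfinite(loglik):
            raise ValueError(f"pair {idx} impossible under model (log-likelihood -inf)")
        beta = _dp.backward_kernel(
            kind, logA, logtau, logEx, logEr, logEmv, robs, pair.Tx, pair.Tr, W,
            lagmin, lagmax,
        )
        with np.errstate(invalid="ignore"):
            g = alpha + beta - loglik
        gamma = np.exp(np.where(np.isneginf(alpha), -np.inf, g))
        gamma[np.isnan(gamma)] = 0.0
        fld = PosteriorField(
            gamma=gamma,
            Tx=pair.Tx,
            Tr=pair.Tr,
            band_width=W,
            log_likelihood=float(loglik),
        )
        xiA = _dp.transition_stats_kernel(
            kind, logA, logEx, logEr, logEmv, robs, pair.Tx, pair.Tr, W, alpha, beta,
            loglik, lagmin, lagmax,
        )
        N = model.n_states
        start = np.zeros(N)
        term = np.zeros(N)
        first_cell = {0: (1, 0), 1: (0, 1), 2: (1, 1)}
        for s in range(N):
            ci, cj = first_cell[int(kind[s])]
            try:
                start[s] = fld.at(ci, cj, s)
            except IndexError:  # W = 0 and X/R first step leaves the band
                start[s] = 0.0
            term[s] = fld.at(pair.Tx, pair.Tr, s)
        out.append(
            PairStatistics(
                field=fld,
                transitions=TransitionPosteriors(xiA, start, term),
                log_likelihood=float(loglik),
            )
        )
    return out


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def _floor_covariance(C: np.ndarray, rel_floor: float) -> np.ndarray:
    floor = rel_floor * float(np.mean(np.diag(C)))
    floor = max(floor, rel_floor * 1e-3)
    w, U = np.linalg.eigh((C + C.T) / 2.0)
    w = np.maximum(w, floor)
    return (U * w) @ U.T


def _update_gmm(
    em: GaussianMixtureEmission,
    data: list[tuple[np.ndarray, np.ndarray]],
    rel_floor: float,
) -> None:
    """Responsibility-weighted moment update of one Gaussian mixture.

    ``data`` is a list of (embedded stimuli, occupancy weights) per pair;
    constraint flags decide which freshly estimated moments are kept.
    """
    K, d = em.n_components, em.dim
    free_mean = em.mean_mode == "free"
    free_cov = em.covariance_mode == "free"
    if not free_mean and not free_cov and K == 1:
        return  # fully constrained
    S0 = np.zeros(K)
    S1 = np.zeros((K, d))
    S2 = np.zeros((K, d, d))
    with np.errstate(divide="ignore"):
        logw = np.log(em.weights)
    for X, w in data:
        idx = np.flatnonzero(w > 0)
        if idx.size == 0:
            continue
        Xs, ws = X[idx], w[idx]
        if K == 1:
            r = ws[:, None]
        else:
            lp = em.component_log_pdfs(Xs) + logw[None, :]
            m = lp.max(axis=1, keepdims=True)
            q = np.exp(lp - m)
            q /= q.sum(axis=1, keepdims=True)
            r = ws[:, None] * q
        S0 += r.sum(axis=0)
        S1 += r.T @ Xs
        if free_cov:
            for k in range(K):
                S2[k] += (Xs * r[:, k : k + 1]).T @ Xs
    total = S0.sum()
    if total <= 0:
        warnings.warn("Gaussian mixture received no occupancy; left unchanged")
        return
    if K > 1:
        empty = S0 <= 0
        if np.any(empty):
            warnings.warn(
                f"{int(empty.sum())} mixture component(s) collapsed (zero responsibility)"
            )
        em.weights = S0 / total
    for k in range(K):
        if S0[k] <= 0:
            continue
        mu = S1[k] / S0[k]
        if free_mean:
            em.means[k] = mu
        if free_cov:
            C = S2[k] / S0[k] - np.outer(mu, mu)
            if not free_mean:
                diff = mu - em.means[k]
                C = C + np.outer(diff, diff)
            em.covariances[k] = _floor_covariance(C, rel_floor)


def m_step(
    model: MPHModel,
    pairs: list[StimulusResponsePair],
    stats: list[PairStatistics],
    config: EMConfig | None = None,
) -> MPHModel:
    """Re-estimate all free parameters from pooled E-step statistics."""
    config = config or EMConfig()
    new = model.copy()
    N = model.n_states
    kinds = model.kinds

    xiA = np.zeros((N, N))
    start = np.zeros(N)
    term = np.zeros(N)
    for st in stats:
        xiA += st.transitions.xi_sums
        start += st.transitions.start_occupancy
        term += st.transitions.terminal_occupancy

    for s in range(N):
        denom = xiA[s].sum() + term[s]
        if denom <= 0:
            continue  # state unused: keep old row
        if not config.freeze_transitions:
            if config.freeze_final:
                row_mass = xiA[s].sum()
                if row_mass > 0:
                    new.transitions[s] = xiA[s] / row_mass * (1.0 - new.final[s])
            else:
                new.transitions[s] = xiA[s] / denom
        if not config.freeze_final:
            new.final[s] = term[s] / denom
            if config.freeze_transitions:
                # keep the row consistent with the frozen transitions
                new.final[s] = 1.0 - new.transitions[s].sum()
    if not config.freeze_initial and start.sum() > 0:
        new.initial = start / start.sum()

    if config.freeze_emissions:
        return new

    # per-state occupancy weights over positions, split by response symbol
    V = model.n_symbols
    for s in range(N):
        st_new = new.states[s]
        if kinds[s] == 0:  # X-state: weights over stimulus positions
            data = []
            for pair, ps in zip(pairs, stats):
                w = ps.field.gamma[1:, :, s].sum(axis=1)  # (Tx,)
                data.append((pair.stimulus, w))
            _update_gmm(st_new.emission, data, config.cov_eigenvalue_floor)
        elif kinds[s] == 1:  # R-state: symbol counts
            if st_new.emission.frozen:
                continue
            counts = np.zeros(V)
            for pair, ps in zip(pairs, stats):
                sym = _band_symbols(pair.response, pair.Tx, ps.field.band_width)
                g = ps.field.gamma[:, :, s]
                for v in range(V):
                    counts[v] += g[sym == v].sum()
            if counts.sum() > 0:
                st_new.emission.probs = counts / counts.sum()
        else:  # M-state: marginal + one conditional mixture per symbol
            counts = np.zeros(V)
            per_v_data: list[list[tuple[np.ndarray, np.ndarray]]] = [[] for _ in range(V)]
            for pair, ps in zip(pairs, stats):
                sym = _band_symbols(pair.response, pair.Tx, ps.field.band_width)
                g = ps.field.gamma[:, :, s]
                for v in range(V):
                    mask = sym == v
                    counts[v] += g[mask].sum()
                    w = np.where(mask, g, 0.0).sum(axis=1)[1:]  # (Tx,)
                    per_v_data[v].append((pair.stimulus, w))
            if not st_new.emission.response_marginal.frozen and counts.sum() > 0:
                st_new.emission.response_marginal.probs = counts / counts.sum()
            for v in range(V):
                _update_gmm(
                    st_new.emission.conditional_stimulus[v],
                    per_v_data[v],
                    config.cov_eigenvalue_floor,
                )
    return new


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def spike_triggered_mean(pairs: list[StimulusResponsePair]) -> np.ndarray:
    """Mean embedded stimulus at spike bins, pairing the sequences diagonally."""
    num = None
    n = 0.0
    for pair in pairs:
        T = min(pair.Tx, pair.Tr)
        w = (pair.response[:T] > 0).astype(float)
        v = w @ pair.stimulus[:T]
        num = v if num is None else num + v
        n += w.sum()
    if n == 0:
        raise ValueError("no spikes in training pairs")
    return num / n


def initialize_model(
    template: MPHModel,
    pairs: list[StimulusResponsePair],
    rng: np.random.Generator,
    config: EMConfig | None = None,
) -> MPHModel:
    """Draw a randomized starting point around data statistics.

    Transitions/initial/final get Dirichlet jitter around the template rows;
    free spike-conditioned means start at the spike-triggered mean plus
    Gaussian noise (which breaks symmetry between multiple M-states); free
    no-spike/X means start at the stimulus mean; free marginals at the
    empirical spike rate.
    """
    config = config or EMConfig()
    m = template.copy()
    N = m.n_states
    c = config.init_transition_concentration
    for s in range(N):
        base = np.concatenate([m.transitions[s], [m.final[s]]])
        row = rng.dirichlet(np.maximum(base, 0.02) * c)
        m.transitions[s] = row[:N]
        m.final[s] = row[N]
    m.initial = rng.dirichlet(np.maximum(m.initial, 0.02) * c)

    stim_mean = np.mean([pair.stimulus.mean(axis=0) for pair in pairs], axis=0)
    n_bins = sum(pair.Tr for pair in pairs)
    n_spikes = sum(int((pair.response > 0).sum()) for pair in pairs)
    rate = min(max(n_spikes / max(n_bins, 1), 1e-6), 1 - 1e-6)
    try:
        sta = spike_triggered_mean(pairs)
    except ValueError:
        sta = stim_mean
    scale = config.init_mean_noise * max(float(np.std(sta)), 1e-3)

    for st in m.states:
        if st.kind == "X":
            if st.emission.mean_mode == "free":
                st.emission.means[:] = stim_mean[None, :] + rng.normal(
                    scale=scale, size=st.emission.means.shape
                )
        elif st.kind == "M":
            em = st.emission
            if not em.response_marginal.frozen and em.n_symbols == 2:
                em.response_marginal.probs = np.array([1.0 - rate, rate])
            for v, g in enumerate(em.conditional_stimulus):
                if g.mean_mode == "free":
                    center = sta if v > 0 else stim_mean
                    g.means[:] = center[None, :] + rng.normal(
                        scale=scale, size=g.means.shape
                    )
    return m


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def em_fit(
    model: MPHModel,
    pairs: list[StimulusResponsePair],
    config: EMConfig | None = None,
) -> tuple[MPHModel, np.ndarray, dict]:
    """Fit by EM; returns (fitted model, log-likelihood trace, diagnostics).

    With ``n_restarts > 1`` the first restart starts from ``model`` as given
    and the others from :func:`initialize_model` jitters of it; the restart
    with the highest training log-likelihood wins.  The returned trace is
    the winner's; ``diagnostics['restarts']`` tabulates all of them.
    """
    config = config or EMConfig()
    problems = validate_model(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)

    best: tuple[float, MPHModel, np.ndarray] | None = None
    table = []
    errors = []
    for r in range(config.n_restarts):
        try:
            start_model = (
                model.copy() if r == 0 else initialize_model(model, pairs, rng, config)
            )
            fitted, trace = _fit_once(start_model, pairs, config)
        except Exception as exc:  # noqa: BLE001 - collected into diagnostics
            errors.append(f"restart {r}: {exc}")
            table.append({"restart": r, "log_likelihood": None, "iterations": 0})
            continue
        final_ll = float(trace[-1])
        table.append(
            {"restart": r, "log_likelihood": final_ll, "iterations": len(trace)}
        )
        if best is None or final_ll > best[0]:
            best = (final_ll, fitted, trace)
    if best is None:
        raise RuntimeError("all EM restarts failed: " + "; ".join(errors))
    _, fitted, trace = best
    diagnostics = {"restarts": table, "errors": errors, "n_pairs": len(pairs)}
    return fitted, trace, diagnostics


def _fit_once(
    model: MPHModel, pairs: list[StimulusResponsePair], config: EMConfig
) -> tuple[MPHModel, np.ndarray]:
    trace = []
    prev = -np.inf
    for _ in range(config.max_iters):
        stats = e_step(model, pairs)
        ll = float(sum(s.log_likelihood for s in stats))
        trace.append(ll)
        if np.isfinite(prev):
            rel = (ll - prev) / max(abs(prev), 1.0)
            if rel < config.loglik_rel_tol:
                break
        model = m_step(model, pairs, stats, config)
        prev = ll
    return model, np.asarray(trace)
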