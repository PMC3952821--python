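"""Banded alignment-tensor algorithms: forward, backward, Viterbi,
posteriors, and alignment kernels.

A hidden-state sequence of an MPH is a monotone path through the
(stimulus position, response position) lattice from (0, 0) to (Tx, Tr):
M-states step diagonally, X-states horizontally, R-states vertically.  The
dynamic programs below run over the band ``|i - j| <= W`` in the log domain
and are exact whenever all path mass lies inside the band (always true for
``W >= max(Tx, Tr)``).

``enumerate_paths_bruteforce`` is an independent exponential-time oracle
used by the test-suite to certify the recursions on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dp
from .model import MPHModel, StimulusResponsePair

__all__ = [
    "AlignmentTensors",
    "PosteriorField",
    "AlignmentKernel",
    "HiddenPath",
    "forward",
    "backward",
    "forward_backward",
    "viterbi",
    "posteriors",
    "alignment_kernel",
    "enumerate_paths_bruteforce",
]

_STEP = {"X": (1, 0), "R": (0, 1), "M": (1, 1)}


@dataclass
class AlignmentTensors:
    """Banded log-domain DP quantities.

    Arrays have shape ``(Tx + 1, 2 W + 1, N)``; slot ``k`` of row ``i``
    addresses response position ``j = i + k - W``.  Entries outside the band
    are ``-inf``.
    """

    Tx: int
    Tr: int
    band_width: int
    log_forward: np.ndarray | None = None
    log_backward: np.ndarray | None = None
    log_viterbi: np.ndarray | None = None
    pointers: np.ndarray | None = None
    log_likelihood: float | None = None

    def slot(self, i: int, j: int) -> int:
        k = j - i + self.band_width
        if not 0 <= k <= 2 * self.band_width:
            raise IndexError(f"(i={i}, j={j}) outside band W={self.band_width}")
        return k

    def alpha(self, i: int, j: int, s: int) -> float:
        return float(self.log_forward[i, self.slot(i, j), s])

    def beta(self, i: int, j: int, s: int) -> float:
        return float(self.log_backward[i, self.slot(i, j), s])


@dataclass
class PosteriorField:
    """Posterior state probabilities gamma over banded (i, j, s)."""

    gamma: np.ndarray  # (Tx + 1, 2W + 1, N)
    Tx: int
    Tr: int
    band_width: int
    log_likelihood: float

    def at(self, i: int, j: int, s: int) -> float:
        k = j - i + self.band_width
        if not 0 <= k <= 2 * self.band_width:
            return 0.0
        return float(self.gamma[i, k, s])


@dataclass
class AlignmentKernel:
    """Posterior distribution over stimulus-response lags.

    ``lag = j - i`` in response bins: negative lags mean the spike occurs
    before its matched stimulus position.
    """

    lags: np.ndarray  # integers -W..W
    probs: np.ndarray
    bin_width: float = 1.0

    @property
    def lags_seconds(self) -> np.ndarray:
        return self.lags * self.bin_width

    def mean_lag(self) -> float:
        return float(np.dot(self.lags, self.probs))

    def mode_lag(self) -> int:
        return int(self.lags[np.argmax(self.probs)])


@dataclass
class HiddenPath:
    """A hidden-state sequence with its implied lattice trajectory."""

    states: list[int]
    kinds: list[str]

    @property
    def trajectory(self) -> list[tuple[int, int]]:
        pos = [(0, 0)]
        for kd in self.kinds:
            di, dj = _STEP[kd]
            i, j = pos[-1]
            pos.append((i + di, j + dj))
        return pos

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# emission tables
# ---------------------------------------------------------------------------


def _emission_tables(model: MPHModel, pair: StimulusResponsePair, marginalize_response=False):
    """Precompute per-position log emissions for the DP kernels.

    Returns ``(logEx, logEr, logEmv, robs)`` with 1-based position rows (row
    0 unused).  With ``marginalize_response`` the response is treated as
    unobserved: R-state emissions sum out to 1 (only valid for models
    without M-states, i.e. after rewriting).
    """
    Tx, Tr, N = pair.Tx, pair.Tr, model.n_states
    V = model.n_symbols
    X = pair.stimulus
    logEx = np.full((Tx + 1, N), -np.inf)
    logEr = np.full((Tr + 1, N), -np.inf)
    logEmv = np.full((Tx + 1, V, N), -np.inf)
    robs = np.zeros(Tr + 1, dtype=np.int64)
    if not marginalize_response:
        if np.any(pair.response < 0) or np.any(pair.response >= V):
            raise ValueError(f"response symbols must lie in 0..{V - 1}")
        robs[1:] = pair.response
    for s, st in enumerate(model.states):
        if st.kind == "X":
            if st.emission.dim != pair.dim:
                raise ValueError(
                    f"state {s}: emission dim {st.emission.dim} != stimulus dim {pair.dim}"
                )
            logEx[1:, s] = st.emission.log_pdf(X)
        elif st.kind == "R":
            if marginalize_response:
                logEr[1:, s] = 0.0
            else:
                lp = st.emission.log_probs()
                logEr[1:, s] = lp[pair.response]
        else:
            if marginalize_response:
                raise ValueError(
                    "cannot marginalize the response of a model with M-states; "
                    "rewrite it first (encoding.rewrite_for_inference)"
                )
            em = st.emission
            if em.dim != pair.dim:
                raise ValueError(
                    f"state {s}: emission dim {em.dim} != stimulus dim {pair.dim}"
                )
            lp = em.response_marginal.log_probs()
            for v in range(V):
                if np.isfinite(lp[v]):
                    logEmv[1:, v, s] = lp[v] + em.conditional_stimulus[v].log_pdf(X)
    return logEx, logEr, logEmv, robs


def _check_connectivity(model: MPHModel, Tx: int, Tr: int, W: int) -> None:
    kinds = {st.kind for st in model.states}
    if abs(Tx - Tr) > W:
        raise ValueError(
            f"band width {W} too narrow to connect (0,0) to ({Tx},{Tr})"
        )
    if Tx > Tr and "X" not in kinds and Tx - Tr > 0:
        raise ValueError("stimulus longer than response but model has no X-state")
    if Tr > Tx and "R" not in kinds and Tr - Tx > 0:
        raise ValueError("response longer than stimulus but model has no R-state")
    if "M" not in kinds:
        if "X" not in kinds and Tx > 0:
            raise ValueError("model cannot consume the stimulus sequence")
        if "R" not in kinds and Tr > 0:
            raise ValueError("model cannot consume the response sequence")


def _lag_bounds(model, W: int) -> tuple[np.ndarray, np.ndarray]:
    if model.lag_bounds is None:
        N = model.n_states
        return np.full(N, -W, dtype=np.int64), np.full(N, W, dtype=np.int64)
    return (
        model.lag_bounds[:, 0].astype(np.int64),
        model.lag_bounds[:, 1].astype(np.int64),
    )


def _prep(model, pair, marginalize_response=False):
    W = int(model.band_width)
    _check_connectivity(model, pair.Tx, pair.Tr, W)
    logEx, logEr, logEmv, robs = _emission_tables(model, pair, marginalize_response)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transitions)
        logrho = np.log(model.initial)
        logtau = np.log(model.final)
    lagmin, lagmax = _lag_bounds(model, W)
    return (
        model.kinds, logA, logrho, logtau, logEx, logEr, logEmv, robs, W, lagmin, lagmax
    )


# ---------------------------------------------------------------------------
# DP wrappers
# ---------------------------------------------------------------------------


def forward(
    model: MPHModel, pair: StimulusResponsePair, marginalize_response: bool = False
) -> AlignmentTensors:
    """Generalized forward recursion; fills alpha and the log likelihood."""
    (kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, W, lagmin, lagmax) = _prep(
        model, pair, marginalize_response
    )
    alpha, loglik = _dp.forward_kernel(
        kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, pair.Tx, pair.Tr, W,
        lagmin, lagmax,
    )
    return AlignmentTensors(
        Tx=pair.Tx,
        Tr=pair.Tr,
        band_width=W,
        log_forward=alpha,
        log_likelihood=float(loglik),
    )


def backward(
    model: MPHModel, pair: StimulusResponsePair, marginalize_response: bool = False
) -> AlignmentTensors:
    """Generalized backward recursion; beta at (Tx, Tr) equals tau."""
    (kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, W, lagmin, lagmax) = _prep(
        model, pair, marginalize_response
    )
    beta = _dp.backward_kernel(
        kind, logA, logtau, logEx, logEr, logEmv, robs, pair.Tx, pair.Tr, W,
        lagmin, lagmax,
    )
    return AlignmentTensors(Tx=pair.Tx, Tr=pair.Tr, band_width=W, log_backward=beta)


def forward_backward(
    model: MPHModel, pair: StimulusResponsePair, marginalize_response: bool = False
) -> AlignmentTensors:
    """Both recursions on shared emission tables (one table build)."""
    (kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, W, lagmin, lagmax) = _prep(
        model, pair, marginalize_response
    )
    alpha, loglik = _dp.forward_kernel(
        kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, pair.Tx, pair.Tr, W,
        lagmin, lagmax,
    )
    beta = _dp.backward_kernel(
        kind, logA, logtau, logEx, logEr, logEmv, robs, pair.Tx, pair.Tr, W,
        lagmin, lagmax,
    )
    return AlignmentTensors(
        Tx=pair.Tx,
        Tr=pair.Tr,
        band_width=W,
        log_forward=alpha,
        log_backward=beta,
        log_likelihood=float(loglik),
    )


def viterbi(model: MPHModel, pair: StimulusResponsePair) -> tuple[HiddenPath, float]:
    """Most likely hidden path and its joint log probability."""
    (kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, W, lagmin, lagmax) = _prep(
        model, pair
    )
    delta, ptr, best_end, best_val = _dp.viterbi_kernel(
        kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, pair.Tx, pair.Tr, W,
        lagmin, lagmax,
    )
    if best_end < 0 or best_val == -np.inf:
        raise ValueError("pair impossible under model (zero probability)")
    kind_char = {0: "X", 1: "R", 2: "M"}
    states: list[int] = []
    i, j, s = pair.Tx, pair.Tr, int(best_end)
    while True:
        states.append(s)
        k = j - i + W
        prev = int(ptr[i, k, s])
        di, dj = _STEP[kind_char[int(kind[s])]]
        i, j = i - di, j - dj
        if prev == -1:
            break
        s = prev
    states.reverse()
    path = HiddenPath(states=states, kinds=[kind_char[int(kind[s])] for s in states])
    return path, float(best_val)


def posteriors(
    model: MPHModel,
    pair: StimulusResponsePair,
    tensors: AlignmentTensors | None = None,
    marginalize_response: bool = False,
) -> PosteriorField:
    """Posterior state probabilities gamma = exp(alpha + beta - log P)."""
    if tensors is None or tensors.log_forward is None or tensors.log_backward is None:
        tensors = forward_backward(model, pair, marginalize_response)
    loglik = tensors.log_likelihood
    if loglik is None or loglik == -np.inf:
        raise ValueError("pair impossible under model (zero probability)")
    with np.errstate(invalid="ignore"):
        g = tensors.log_forward + tensors.log_backward - loglik
    gamma = np.exp(np.where(np.isneginf(tensors.log_forward), -np.inf, g))
    gamma[np.isnan(gamma)] = 0.0
    return PosteriorField(
        gamma=gamma,
        Tx=tensors.Tx,
        Tr=tensors.Tr,
        band_width=tensors.band_width,
        log_likelihood=loglik,
    )


def _band_symbols(response: np.ndarray, Tx: int, W: int) -> np.ndarray:
    """Map banded slots to 1-based response symbols (-1 outside/zero row)."""
    Tr = len(response)
    sym = np.full((Tx + 1, 2 * W + 1), -1, dtype=np.int64)
    i = np.arange(Tx + 1)[:, None]
    j = i + np.arange(-W, W + 1)[None, :]
    ok = (j >= 1) & (j <= Tr)
    sym[ok] = response[j[ok] - 1]
    return sym


def alignment_kernel(
    model: MPHModel,
    pair: StimulusResponsePair,
    field: PosteriorField | None = None,
    include_r_states: bool = False,
) -> AlignmentKernel:
    """Posterior-weighted histogram of spike lags (the jitter estimate).

    Sums M-state posteriors over banded cells ``(i, j)`` whose response
    symbol is a spike, binned by lag ``j - i``, and normalizes to a
    probability vector.  ``include_r_states`` additionally counts R-state
    posteriors at spike positions (only meaningful for models whose R-states
    can emit spikes).
    """
    if not np.any(pair.response > 0):
        raise ValueError("kernel undefined: pair contains no spikes")
    if field is None:
        field = posteriors(model, pair)
    W = field.band_width
    kinds = model.kinds
    sel = kinds == 2
    if include_r_states:
        sel = sel | (kinds == 1)
    mass = field.gamma[:, :, sel].sum(axis=2)  # (Tx+1, 2W+1)
    sym = _band_symbols(pair.response, field.Tx, W)
    mass = np.where(sym > 0, mass, 0.0)
    by_lag = mass.sum(axis=0)  # slot k <-> lag k - W
    total = by_lag.sum()
    if total <= 0:
        raise ValueError("kernel undefined: no posterior mass at spike positions")
    return AlignmentKernel(
        lags=np.arange(-W, W + 1), probs=by_lag / total, bin_width=pair.bin_width
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def enumerate_paths_bruteforce(
    model: MPHModel,
    pair: StimulusResponsePair,
    max_paths: int = 200_000,
) -> tuple[list[tuple[HiddenPath, float]], float]:
    """Exhaustively enumerate all banded hidden paths with exact probabilities.

    Independent of the DP code: walks the lattice recursively, multiplying
    initial, transition, emission, and final probabilities in the linear
    domain.  Intended for tiny instances only; raises once ``max_paths``
    complete paths have been found.
    """
    Tx, Tr, W = pair.Tx, pair.Tr, int(model.band_width)
    _check_connectivity(model, Tx, Tr, W)
    N = model.n_states
    kind_char = [st.kind for st in model.states]
    # linear-domain per-position emissions
    ex = np.zeros((Tx + 1, N))
    er = np.zeros((Tr + 1, N))
    emr = np.zeros((Tx + 1, Tr + 1, N))
    for s, st in enumerate(model.states):
        if st.kind == "X":
            ex[1:, s] = np.exp(st.emission.log_pdf(pair.stimulus))
        elif st.kind == "R":
            er[1:, s] = st.emission.probs[pair.response]
        else:
            marg = st.emission.response_marginal.probs
            for j in range(1, Tr + 1):
                v = pair.response[j - 1]
                if marg[v] > 0:
                    emr[1:, j, s] = marg[v] * np.exp(
                        st.emission.conditional_stimulus[v].log_pdf(pair.stimulus)
                    )

    results: list[tuple[HiddenPath, float]] = []

    def recurse(i: int, j: int, s: int, prob: float, states: list[int]) -> None:
        if prob == 0.0:
            return
        if i == Tx and j == Tr:
            p_end = prob * model.final[s]
            if p_end > 0:
                if len(results) >= max_paths:
                    raise RuntimeError(f"path cap {max_paths} exceeded")
                results.append(
                    (
                        HiddenPath(
                            states=list(states), kinds=[kind_char[q] for q in states]
                        ),
                        p_end,
                    )
                )
        for sn in range(N):
            a = model.transitions[s, sn]
            if a == 0.0:
                continue
            _advance(i, j, sn, prob * a, states)

    def _advance(i: int, j: int, sn: int, base: float, states: list[int]) -> None:
        kd = kind_char[sn]
        di, dj = _STEP[kd]
        ni, nj = i + di, j + dj
        if ni > Tx or nj > Tr or abs(ni - nj) > W:
            return
        if kd == "X":
            e = ex[ni, sn]
        elif kd == "R":
            e = er[nj, sn]
        else:
            e = emr[ni, nj, sn]
        states.append(sn)
        recurse(ni, nj, sn, base * e, states)
        states.pop()

    for s0 in range(N):
        rho = model.initial[s0]
        if rho > 0:
            _advance(0, 0, s0, rho, [])

    total = float(sum(p for _, p in results))
    return results, total
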