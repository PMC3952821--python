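"""Encoding: predicting spike responses from stimuli.

Three routes are provided:

* :func:`encode_map` — the extended Viterbi recursion that returns the
  jointly most likely (hidden path, response sequence) for a stimulus;
* :func:`response_probabilities` — per-bin spike probabilities obtained by
  rewriting every M-state into X/R branch states
  (:func:`rewrite_for_inference`) and running forward-backward with the
  response marginalized out;
* the cascade (:func:`fit_cascade` / :func:`apply_cascade`) — a
  histogram-ratio output nonlinearity remapping posterior spike
  probabilities, turning the model into an NNP (nonlinear-nonlinear-
  Poisson) cascade.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import _dp
from .alignment import HiddenPath, posteriors
from .model import (
    DiscreteEmission,
    MPHModel,
    StateSpec,
    StimulusResponsePair,
)

__all__ = [
    "ResponseProbabilitySeries",
    "CascadeMapping",
    "encode_map",
    "rewrite_for_inference",
    "response_probabilities",
    "fit_cascade",
    "apply_cascade",
]


@dataclass
class ResponseProbabilitySeries:
    """Per-bin distributions over the response alphabet."""

    probs: np.ndarray  # (Tr, V), rows sum to 1
    bin_width: float = 1.0

    @property
    def spike_prob(self) -> np.ndarray:
        """P(at least one spike) per bin."""
        return 1.0 - self.probs[:, 0]

    @property
    def rate_hz(self) -> np.ndarray:
        return self.spike_prob / self.bin_width


@dataclass
class CascadeMapping:
    """Estimated output nonlinearity g(p) on posterior spike probability.

    ``values[b] = spike-coincident count / total count`` in probability bin
    ``b``; empty bins are filled by linear interpolation from neighbors.
    Application interpolates linearly between bin centers.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return np.clip(np.interp(p, self.centers, self.values), 0.0, 1.0)


# ---------------------------------------------------------------------------
# extended Viterbi encoding
# ---------------------------------------------------------------------------


def encode_map(
    model: MPHModel, stimulus: np.ndarray, Tr: int | None = None
) -> tuple[np.ndarray, HiddenPath, float]:
    """Jointly most likely (response, hidden path) for a given stimulus.

    At every response-consuming step the symbol maximizing the emission
    probability is taken; backtracking recovers both sequences.  ``Tr``
    defaults to the stimulus length.
    """
    stimulus = np.atleast_2d(np.asarray(stimulus, dtype=float))
    Tx = stimulus.shape[0]
    if Tr is None:
        Tr = Tx
    V = model.n_symbols
    N = model.n_states
    W = int(model.band_width)
    pair = StimulusResponsePair(stimulus, np.zeros(Tr, dtype=int))

    from .alignment import _check_connectivity, _emission_tables

    _check_connectivity(model, Tx, Tr, W)
    logEx, _, logEmv, _ = _emission_tables(model, pair)
    logPr = np.full((N, V), -np.inf)
    for s, st in enumerate(model.states):
        if st.kind == "R":
            logPr[s] = st.emission.log_probs()
    with np.errstate(divide="ignore"):
        logA = np.log(model.transitions)
        logrho = np.log(model.initial)
        logtau = np.log(model.final)
    kind = model.kinds
    from .alignment import _lag_bounds

    lagmin, lagmax = _lag_bounds(model, W)
    _, ptr, sym, best_end, best_val = _dp.encode_kernel(
        kind, logA, logrho, logtau, logEx, logPr, logEmv, Tx, Tr, W, lagmin, lagmax
    )
    if best_end < 0 or best_val == -np.inf:
        raise ValueError("no admissible (path, response) pair under model")
    kind_char = {0: "X", 1: "R", 2: "M"}
    step = {"X": (1, 0), "R": (0, 1), "M": (1, 1)}
    states: list[int] = []
    response = np.zeros(Tr, dtype=np.int64)
    i, j, s = Tx, Tr, int(best_end)
    while True:
        states.append(s)
        k = j - i + W
        kd = kind_char[int(kind[s])]
        if kd in ("R", "M"):
            response[j - 1] = sym[i, k, s]
        prev = int(ptr[i, k, s])
        di, dj = step[kd]
        i, j = i - di, j - dj
        if prev == -1:
            break
        s = prev
    states.reverse()
    path = HiddenPath(states=states, kinds=[kind_char[int(kind[q])] for q in states])
    return response, path, float(best_val)


# ---------------------------------------------------------------------------
# M-state rewriting
# ---------------------------------------------------------------------------


def _is_stochastic_r(st: StateSpec) -> bool:
    p = st.emission.probs
    return bool(p.min() > 0.0)


def rewrite_for_inference(model: MPHModel) -> MPHModel:
    """Split every M-state into X/R branch states (binary response only).

    Each M-state becomes up to two chains ``x_v -> r_v`` (v = no-spike /
    spike): the branch X-state carries the spike-conditioned Gaussian, the
    deterministic branch R-state consumes the response symbol, and incoming
    transitions are split by the M-state's response marginal.  Stochastic
    R-states are likewise split into never-spike / always-spike branches.
    Zero-probability branches are pruned.  The rewritten model assigns the
    same probability to every stimulus-response pair as the original; it is
    the form used for response-probability inference, where the response is
    left unobserved.  Models with no M-states and no stochastic R-states are
    returned unchanged.
    """
    if model.n_symbols != 2:
        raise ValueError("rewriting is defined for binary responses (V = 2) only")
    needs = any(st.kind == "M" for st in model.states) or any(
        st.kind == "R" and _is_stochastic_r(st) for st in model.states
    )
    if not needs:
        return model

    W = int(model.band_width)
    if model.lag_bounds is None:
        base_lo = np.full(model.n_states, -W, dtype=np.int64)
        base_hi = np.full(model.n_states, W, dtype=np.int64)
    else:
        base_lo = model.lag_bounds[:, 0].copy()
        base_hi = model.lag_bounds[:, 1].copy()

    new_states: list[StateSpec] = []
    new_bounds: list[tuple[int, int]] = []
    in_ports: list[list[tuple[int, float]]] = []  # per original state
    out_ports: list[list[int]] = []
    internal: list[tuple[int, int]] = []  # x_v -> r_v probability-1 arcs

    for s_idx, st in enumerate(model.states):
        ports_in: list[tuple[int, float]] = []
        ports_out: list[int] = []
        if st.kind == "X":
            idx = len(new_states)
            new_states.append(copy.deepcopy(st))
            new_bounds.append((base_lo[s_idx], base_hi[s_idx]))
            ports_in.append((idx, 1.0))
            ports_out.append(idx)
        elif st.kind == "R":
            if _is_stochastic_r(st):
                for v in (0, 1):
                    p = float(st.emission.probs[v])
                    if p == 0.0:
                        continue
                    idx = len(new_states)
                    probs = np.zeros(2)
                    probs[v] = 1.0
                    new_states.append(
                        StateSpec(
                            kind="R",
                            emission=DiscreteEmission(probs, frozen=True),
                            label=f"{st.label or 'R'}|r{v}",
                        )
                    )
                    new_bounds.append((base_lo[s_idx], base_hi[s_idx]))
                    ports_in.append((idx, p))
                    ports_out.append(idx)
            else:
                idx = len(new_states)
                new_states.append(copy.deepcopy(st))
                new_bounds.append((base_lo[s_idx], base_hi[s_idx]))
                ports_in.append((idx, 1.0))
                ports_out.append(idx)
        else:  # M-state
            marg = st.emission.response_marginal.probs
            for v in (0, 1):
                p = float(marg[v])
                if p == 0.0:
                    continue
                x_idx = len(new_states)
                new_states.append(
                    StateSpec(
                        kind="X",
                        emission=copy.deepcopy(st.emission.conditional_stimulus[v]),
                        label=f"{st.label or 'M'}|x{v}",
                    )
                )
                # intermediate x-branch cell sits one lag below the M cell
                new_bounds.append((base_lo[s_idx] - 1, base_hi[s_idx] - 1))
                r_idx = len(new_states)
                probs = np.zeros(2)
                probs[v] = 1.0
                new_states.append(
                    StateSpec(
                        kind="R",
                        emission=DiscreteEmission(probs, frozen=True),
                        label=f"{st.label or 'M'}|r{v}",
                    )
                )
                new_bounds.append((base_lo[s_idx], base_hi[s_idx]))
                internal.append((x_idx, r_idx))
                ports_in.append((x_idx, p))
                ports_out.append(r_idx)
        in_ports.append(ports_in)
        out_ports.append(ports_out)

    Nn = len(new_states)
    A = np.zeros((Nn, Nn))
    rho = np.zeros(Nn)
    tau = np.zeros(Nn)
    for x_idx, r_idx in internal:
        A[x_idx, r_idx] = 1.0
    for s_orig in range(model.n_states):
        for u in out_ports[s_orig]:
            tau[u] = model.final[s_orig]
            for t_orig in range(model.n_states):
                a = model.transitions[s_orig, t_orig]
                if a == 0.0:
                    continue
                for w_idx, p in in_ports[t_orig]:
                    A[u, w_idx] = a * p
        for w_idx, p in in_ports[s_orig]:
            rho[w_idx] = model.initial[s_orig] * p

    had_m = any(st.kind == "M" for st in model.states)
    return MPHModel(
        states=new_states,
        transitions=A,
        initial=rho,
        final=tau,
        band_width=W + (1 if had_m else 0),
        embedding=model.embedding,
        lag_bounds=np.array(new_bounds, dtype=np.int64),
    )


def _spike_flags(model: MPHModel) -> tuple[np.ndarray, np.ndarray]:
    """Masks of response-consuming states and of those that emit a spike."""
    is_r = np.array([st.kind == "R" for st in model.states])
    spiking = np.array(
        [st.kind == "R" and float(st.emission.probs[0]) < 0.5 for st in model.states]
    )
    return is_r, spiking


def response_probabilities(
    model: MPHModel,
    stimulus: np.ndarray,
    Tr: int | None = None,
    bin_width: float = 1.0,
) -> ResponseProbabilitySeries:
    """Per-bin response distribution P(r_j | stimulus), response unobserved.

    Runs forward-backward on the rewritten model with the discrete response
    emissions marginalized out; the spike probability at response position
    ``j`` is the posterior mass of spike-branch R-states consuming ``j``,
    normalized by the mass of all response-consuming states there.
    """
    stimulus = np.atleast_2d(np.asarray(stimulus, dtype=float))
    Tx = stimulus.shape[0]
    if Tr is None:
        Tr = Tx
    rw = rewrite_for_inference(model)
    pair = StimulusResponsePair(stimulus, np.zeros(Tr, dtype=int), bin_width)
    field = posteriors(rw, pair, marginalize_response=True)
    is_r, spiking = _spike_flags(rw)
    W = field.band_width
    g_all = field.gamma[:, :, is_r].sum(axis=2)  # (Tx+1, 2W+1)
    g_spk = field.gamma[:, :, spiking].sum(axis=2)
    # accumulate banded cells by response position j = i + k - W
    i_idx = np.arange(Tx + 1)[:, None]
    j_idx = i_idx + np.arange(-W, W + 1)[None, :]
    ok = (j_idx >= 1) & (j_idx <= Tr)
    tot = np.zeros(Tr + 1)
    spk = np.zeros(Tr + 1)
    np.add.at(tot, j_idx[ok], g_all[ok])
    np.add.at(spk, j_idx[ok], g_spk[ok])
    tot = tot[1:]
    spk = spk[1:]
    p1 = np.divide(spk, tot, out=np.zeros(Tr), where=tot > 0)
    probs = np.column_stack([1.0 - p1, p1])
    return ResponseProbabilitySeries(probs=probs, bin_width=bin_width)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


def fit_cascade(
    model: MPHModel,
    pairs: list[StimulusResponsePair],
    n_bins: int = 25,
) -> CascadeMapping:
    """Estimate the output nonlinearity by histogram division.

    For every training bin the posterior spike probability ``p`` is
    computed; ``g`` per probability bin is the ratio of the count of bins
    with an actual spike to the total count — the conditional probability of
    a spike given the model's posterior.
    """
    ps = []
    spikes = []
    for pair in pairs:
        series = response_probabilities(
            model, pair.stimulus, pair.Tr, pair.bin_width
        )
        ps.append(series.spike_prob)
        spikes.append(pair.response > 0)
    p = np.concatenate(ps)
    spk = np.concatenate(spikes)
    if not spk.any():
        raise ValueError("cascade undefined: no spikes in training pairs")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    den, _ = np.histogram(p, bins=edges)
    num, _ = np.histogram(p[spk], bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    filled = den > 0
    g = np.zeros(n_bins)
    g[filled] = num[filled] / den[filled]
    if not filled.all():
        if filled.sum() == 0:
            raise ValueError("cascade undefined: no occupied probability bins")
        g[~filled] = np.interp(centers[~filled], centers[filled], g[filled])
    return CascadeMapping(
        bin_edges=edges, values=g, numerator=num.astype(float), denominator=den.astype(float)
    )


def apply_cascade(
    mapping: CascadeMapping,
    series: ResponseProbabilitySeries | np.ndarray,
) -> ResponseProbabilitySeries | np.ndarray:
    """Remap posterior spike probabilities through the estimated nonlinearity."""
    if isinstance(series, ResponseProbabilitySeries):
        p = mapping(series.spike_prob)
        return ResponseProbabilitySeries(
            probs=np.column_stack([1.0 - p, p]), bin_width=series.bin_width
        )
    return mapping(np.asarray(series, dtype=float))
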