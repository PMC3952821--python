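"""Model definitions for mixed pair hidden Markov models (MPHs).

An MPH is a pair HMM that jointly generates a continuous stimulus sequence
(real vectors, e.g. embedded spectrogram windows) and a discrete spike
response sequence.  Three state kinds exist:

* ``M`` (match) states emit a (stimulus, response) pair — a diagonal step in
  the alignment matrix;
* ``X`` states emit only a stimulus vector — a horizontal step;
* ``R`` states emit only a response symbol — a vertical step.

X/R excursions let the model change the running lag between the two
sequences, which is how spike-time jitter and variable response latencies
are represented.  Stimulus emissions are Gaussian mixtures; response
emissions are categorical over ``{0..V-1}`` spikes per bin (``V = 2`` —
spike / no spike — throughout the experiments supported here).

The model terminates through per-state final probabilities ``tau``; each
transition row satisfies ``sum_s' a(s, s') + tau(s) = 1`` so the model is a
proper distribution over finite state paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cholesky, solve_triangular

__all__ = [
    "StimulusEmbeddingSpec",
    "GaussianMixtureEmission",
    "DiscreteEmission",
    "MixedEmission",
    "StateSpec",
    "MPHModel",
    "StimulusResponsePair",
    "embed_stimulus",
    "validate_model",
    "regularize_covariance",
    "build_mxr_template",
    "build_mn_template",
]

_PROB_TOL = 1e-12

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# stimulus embedding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusEmbeddingSpec:
    """How raw ``channels x T`` stimulus matrices map to embedded vectors.

    The embedded vector at bin ``t`` concatenates, channel-major, the
    stimulus columns in the window
    ``[t - window_length + 1 + window_offset, t + window_offset]``
    (zero-padded at the sequence edges).  ``window_offset = 0`` gives a
    causal window ending at ``t``; a systematic mean response lag can be
    absorbed into the offset.
    """

    window_length: int
    window_offset: int = 0
    channels: int = 1

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")

    @property
    def dim(self) -> int:
        return self.channels * self.window_length


def embed_stimulus(stimulus: np.ndarray, spec: StimulusEmbeddingSpec) -> np.ndarray:
    """Embed a raw ``(channels, T)`` stimulus into ``(T, d)`` window vectors."""
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.ndim == 1:
        stimulus = stimulus[None, :]
    if stimulus.shape[0] != spec.channels:
        raise ValueError(
            f"stimulus has {stimulus.shape[0]} channels, embedding expects {spec.channels}"
        )
    T = stimulus.shape[1]
    w, off = spec.window_length, spec.window_offset
    cols = np.arange(T)[:, None] + np.arange(-w + 1 + off, off + 1)[None, :]  # (T, w)
    valid = (cols >= 0) & (cols < T)
    windows = stimulus[:, np.clip(cols, 0, T - 1)]  # (channels, T, w)
    windows = np.where(valid[None, :, :], windows, 0.0)
    return np.ascontiguousarray(windows.transpose(1, 0, 2).reshape(T, spec.dim))


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


@dataclass
class GaussianMixtureEmission:
    """Gaussian-mixture stimulus emission with constraint flags.

    ``covariance_mode``: ``identity`` | ``fixed_shared`` | ``free``;
    ``mean_mode``: ``fixed_zero`` | ``fixed_value`` | ``free``.  Fixed
    parameters are left untouched by the EM M-step.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    covariance_mode: str = "free"
    mean_mode: str = "free"

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def component_log_pdfs(self, X: np.ndarray) -> np.ndarray:
        """Per-component Gaussian log densities, shape ``(T, K)``."""
        X = np.atleast_2d(X)
        T, d = X.shape
        out = np.empty((T, self.n_components))
        for k in range(self.n_components):
            L = cholesky(self.covariances[k], lower=True)
            dev = solve_triangular(L, (X - self.means[k]).T, lower=True)
            maha = np.einsum("ij,ij->j", dev, dev)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            out[:, k] = -0.5 * (d * _LOG2PI + logdet + maha)
        return out

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Mixture log density for each row of ``X``."""
        comp = self.component_log_pdfs(X)
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        lp = comp + logw[None, :]
        m = np.max(lp, axis=1)
        safe = np.where(np.isfinite(m), m, 0.0)
        return safe + np.log(np.sum(np.exp(lp - safe[:, None]), axis=1))


@dataclass
class DiscreteEmission:
    """Categorical response emission over ``{0..V-1}`` spikes per bin."""

    probs: np.ndarray
    frozen: bool = False

    def __post_init__(self) -> None:
        self.probs = np.atleast_1d(np.asarray(self.probs, dtype=float))

    @property
    def n_symbols(self) -> int:
        return len(self.probs)

    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)


@dataclass
class MixedEmission:
    """Joint M-state emission ``e(x, r) = P(r) * p(x | r)``.

    ``response_marginal`` is the categorical over response symbols;
    ``conditional_stimulus[v]`` the Gaussian mixture over stimulus vectors
    given response symbol ``v``.
    """

    response_marginal: DiscreteEmission
    conditional_stimulus: list[GaussianMixtureEmission]

    @property
    def n_symbols(self) -> int:
        return self.response_marginal.n_symbols

    @property
    def dim(self) -> int:
        return self.conditional_stimulus[0].dim


@dataclass
class StateSpec:
    """A hidden state: kind ``X`` / ``R`` / ``M`` plus matching emission."""

    kind: str
    emission: GaussianMixtureEmission | DiscreteEmission | MixedEmission
    label: str = ""


@dataclass
class MPHModel:
    """Full MPH parameter set.

    ``transitions[s, s']`` is the transition probability ``a(s, s')``,
    ``initial`` the start distribution ``rho``, ``final`` the per-state stop
    probabilities ``tau`` (each row of ``transitions`` plus the state's
    ``tau`` sums to one).  ``band_width`` is the maximum |i - j| lag the
    dynamic programs consider.
    """

    states: list[StateSpec]
    transitions: np.ndarray
    initial: np.ndarray
    final: np.ndarray
    band_width: int = 8
    embedding: StimulusEmbeddingSpec | None = None
    #: optional per-state lag bounds, shape (N, 2): [min lag, max lag] of the
    #: cells a state may occupy.  Defaults to the full band +-band_width.
    #: Used by model rewriting to keep banded inference exactly equivalent.
    lag_bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.final = np.asarray(self.final, dtype=float)
        if self.lag_bounds is not None:
            self.lag_bounds = np.asarray(self.lag_bounds, dtype=np.int64)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def kinds(self) -> np.ndarray:
        """State kinds as integers: X=0, R=1, M=2 (the DP kernels' coding)."""
        code = {"X": 0, "R": 1, "M": 2}
        return np.array([code[s.kind] for s in self.states], dtype=np.int64)

    @property
    def n_symbols(self) -> int:
        for s in self.states:
            if s.kind == "R":
                return s.emission.n_symbols
            if s.kind == "M":
                return s.emission.n_symbols
        return 2

    @property
    def dim(self) -> int:
        for s in self.states:
            if s.kind == "X":
                return s.emission.dim
            if s.kind == "M":
                return s.emission.dim
        raise ValueError("model has no stimulus-consuming state")

    def copy(self) -> "MPHModel":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass
class StimulusResponsePair:
    """An embedded stimulus sequence paired with a binned spike response."""

    stimulus: np.ndarray  # (Tx, d)
    response: np.ndarray  # (Tr,) integers in {0..V-1}
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        self.stimulus = np.atleast_2d(np.asarray(self.stimulus, dtype=float))
        self.response = np.asarray(self.response, dtype=np.int64)

    @property
    def Tx(self) -> int:
        return self.stimulus.shape[0]

    @property
    def Tr(self) -> int:
        return len(self.response)

    @property
    def dim(self) -> int:
        return self.stimulus.shape[1]

    @classmethod
    def from_raw(
        cls,
        stimulus_matrix: np.ndarray,
        response: np.ndarray,
        spec: StimulusEmbeddingSpec,
        bin_width: float = 1.0,
    ) -> "StimulusResponsePair":
        return cls(embed_stimulus(stimulus_matrix, spec), response, bin_width)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_gaussian(e: GaussianMixtureEmission, where: str, out: list[str]) -> None:
    if e.n_components < 1:
        out.append(f"{where}: mixture must have K >= 1 components")
        return
    if abs(e.weights.sum() - 1.0) > _PROB_TOL or np.any(e.weights < 0):
        out.append(f"{where}: mixture weights must be >= 0 and sum to 1")
    if e.means.shape[0] != e.n_components or e.covariances.shape[0] != e.n_components:
        out.append(f"{where}: means/covariances do not match component count")
        return
    d = e.dim
    for k in range(e.n_components):
        C = e.covariances[k]
        if C.shape != (d, d):
            out.append(f"{where}: component {k} covariance has wrong shape")
            continue
        if not np.allclose(C, C.T, atol=1e-10):
            out.append(f"{where}: component {k} covariance not symmetric")
            continue
        if np.linalg.eigvalsh(C).min() <= 0:
            out.append(f"{where}: component {k} covariance not positive definite")
    if e.covariance_mode not in ("identity", "fixed_shared", "free"):
        out.append(f"{where}: unknown covariance_mode {e.covariance_mode!r}")
    if e.mean_mode not in ("fixed_zero", "fixed_value", "free"):
        out.append(f"{where}: unknown mean_mode {e.mean_mode!r}")


def _check_discrete(e: DiscreteEmission, where: str, out: list[str]) -> None:
    if abs(e.probs.sum() - 1.0) > _PROB_TOL or np.any(e.probs < 0):
        out.append(f"{where}: response probabilities must be >= 0 and sum to 1")


def validate_model(model: MPHModel) -> list[str]:
    """Return a list of invariant violations (empty iff the model is valid)."""
    out: list[str] = []
    N = model.n_states
    if N == 0:
        return ["model has no states"]
    if model.transitions.shape != (N, N):
        out.append(f"transitions: expected shape ({N}, {N}), got {model.transitions.shape}")
        return out
    if model.initial.shape != (N,) or model.final.shape != (N,):
        out.append("initial/final: wrong shape")
        return out
    if np.any(model.initial < 0) or abs(model.initial.sum() - 1.0) > _PROB_TOL:
        out.append("initial: rho must be >= 0 and sum to 1")
    if np.any(model.transitions < 0) or np.any(model.transitions > 1):
        out.append("transitions: entries must lie in [0, 1]")
    if np.any(model.final < 0) or np.any(model.final > 1):
        out.append("final: tau entries must lie in [0, 1]")
    row_tot = model.transitions.sum(axis=1) + model.final
    for s in np.flatnonzero(np.abs(row_tot - 1.0) > _PROB_TOL):
        out.append(
            f"transitions: row {s} plus final({s}) sums to {row_tot[s]:.12g}, expected 1"
        )
    if model.band_width < 0:
        out.append("band_width: must be >= 0")

    kinds = [s.kind for s in model.states]
    has_m = "M" in kinds
    has_x, has_r = "X" in kinds, "R" in kinds
    if not (has_m or (has_x and has_r)):
        if not has_m and not has_r:
            out.append("state roster: response sequence cannot be consumed")
        elif not has_m and not has_x:
            out.append("state roster: stimulus sequence cannot be consumed")
        else:
            out.append(
                "state roster: need an M-state or both an X- and an R-state to consume both sequences"
            )

    dims: set[int] = set()
    n_syms: set[int] = set()
    for i, st in enumerate(model.states):
        where = f"state {i} ({st.kind}{':' + st.label if st.label else ''})"
        if st.kind == "X":
            if not isinstance(st.emission, GaussianMixtureEmission):
                out.append(f"{where}: X-state requires a Gaussian mixture emission")
                continue
            _check_gaussian(st.emission, where, out)
            dims.add(st.emission.dim)
        elif st.kind == "R":
            if not isinstance(st.emission, DiscreteEmission):
                out.append(f"{where}: R-state requires a discrete emission")
                continue
            _check_discrete(st.emission, where, out)
            n_syms.add(st.emission.n_symbols)
        elif st.kind == "M":
            if not isinstance(st.emission, MixedEmission):
                out.append(f"{where}: M-state requires a mixed emission")
                continue
            _check_discrete(st.emission.response_marginal, where + " marginal", out)
            if len(st.emission.conditional_stimulus) != st.emission.n_symbols:
                out.append(f"{where}: one conditional Gaussian mixture required per symbol")
            for v, g in enumerate(st.emission.conditional_stimulus):
                _check_gaussian(g, f"{where} | r={v}", out)
                dims.add(g.dim)
            n_syms.add(st.emission.n_symbols)
        else:
            out.append(f"{where}: unknown state kind {st.kind!r}")
    if len(dims) > 1:
        out.append(f"emissions: inconsistent stimulus dimensions {sorted(dims)}")
    if len(n_syms) > 1:
        out.append(f"emissions: inconsistent response alphabets {sorted(n_syms)}")
    if model.embedding is not None and dims and model.embedding.dim not in dims:
        out.append(
            f"embedding: dim {model.embedding.dim} does not match emission dim {sorted(dims)}"
        )
    return out


# ---------------------------------------------------------------------------
# covariance regularization
# ---------------------------------------------------------------------------


def regularize_covariance(C: np.ndarray, lam: float) -> np.ndarray:
    """Shrink a covariance toward the scaled identity, preserving the trace.

    Returns ``(1 - lam) * C + lam * (trace(C) / d) * I``.  With PSD ``C``
    every eigenvalue of the result is at least ``lam * trace(C) / d``, which
    is what makes reverse-correlation solves on rank-deficient stimulus
    ensembles well conditioned.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be a square matrix")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    d = C.shape[0]
    return (1.0 - lam) * C + lam * (np.trace(C) / d) * np.eye(d)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


def _fixed_gaussian(mean, cov, cov_mode, mean_mode) -> GaussianMixtureEmission:
    return GaussianMixtureEmission(
        weights=np.array([1.0]),
        means=np.array(mean, dtype=float)[None, :],
        covariances=np.array(cov, dtype=float)[None, :, :],
        covariance_mode=cov_mode,
        mean_mode=mean_mode,
    )


def _resolve_cov(d: int, data_cov, cov_mode: str) -> tuple[np.ndarray, str]:
    if cov_mode == "identity":
        return np.eye(d), "identity"
    if cov_mode == "fixed_shared":
        if data_cov is None:
            raise ValueError("fixed_shared covariance mode requires data_cov")
        data_cov = np.asarray(data_cov, dtype=float)
        if data_cov.shape != (d, d) or not np.allclose(data_cov, data_cov.T, atol=1e-10):
            raise ValueError("data_cov must be a symmetric d x d matrix")
        try:
            cholesky(data_cov, lower=True)
        except np.linalg.LinAlgError:
            raise ValueError("data_cov must be positive definite") from None
        except Exception as exc:  # scipy raises LinAlgError subclasses
            raise ValueError("data_cov must be positive definite") from exc
        return data_cov.copy(), "fixed_shared"
    raise ValueError(f"unknown covariance mode {cov_mode!r}")


def build_mxr_template(
    embedding: StimulusEmbeddingSpec,
    data_mean: np.ndarray | None = None,
    data_cov: np.ndarray | None = None,
    cov_mode: str = "identity",
    spike_rate: float = 0.02,
    band_width: int = 8,
    spike_mean_init: np.ndarray | None = None,
) -> MPHModel:
    """Three-state jitter model: one M-, one X-, one R-state.

    All covariances are fixed (identity or a supplied shared matrix); the X-
    and no-spike M means are fixed to the stimulus ensemble mean; the R-state
    never emits a spike, so every spike must be matched to a stimulus by the
    M-state.  Free parameters: the spike-conditioned M mean (the receptive
    field), the M-state spike marginal, and the transition/initial/final
    probabilities.
    """
    d = embedding.dim
    mean = np.zeros(d) if data_mean is None else np.asarray(data_mean, dtype=float)
    if mean.shape != (d,):
        raise ValueError(f"data_mean must have dimension {d}")
    cov, cmode = _resolve_cov(d, data_cov, cov_mode)
    mean_mode = "fixed_zero" if not mean.any() else "fixed_value"

    spike_mean = (
        mean.copy() if spike_mean_init is None else np.asarray(spike_mean_init, dtype=float)
    )
    m_state = StateSpec(
        kind="M",
        label="M",
        emission=MixedEmission(
            response_marginal=DiscreteEmission(np.array([1.0 - spike_rate, spike_rate])),
            conditional_stimulus=[
                _fixed_gaussian(mean, cov, cmode, mean_mode),
                GaussianMixtureEmission(
                    weights=np.array([1.0]),
                    means=spike_mean[None, :],
                    covariances=cov[None, :, :],
                    covariance_mode=cmode,
                    mean_mode="free",
                ),
            ],
        ),
    )
    x_state = StateSpec(kind="X", label="X", emission=_fixed_gaussian(mean, cov, cmode, mean_mode))
    r_state = StateSpec(
        kind="R", label="R", emission=DiscreteEmission(np.array([1.0, 0.0]), frozen=True)
    )
    # order: M, X, R
    transitions = np.array(
        [
            [0.90, 0.045, 0.045],
            [0.50, 0.300, 0.190],
            [0.50, 0.190, 0.300],
        ]
    )
    final = np.array([0.01, 0.01, 0.01])
    initial = np.array([0.8, 0.1, 0.1])
    return MPHModel(
        states=[m_state, x_state, r_state],
        transitions=transitions,
        initial=initial,
        final=final,
        band_width=band_width,
        embedding=embedding,
    )


def build_mn_template(
    n: int,
    embedding: StimulusEmbeddingSpec,
    spike_rate: float = 0.02,
    cov_mode: str = "identity",
    data_cov: np.ndarray | None = None,
    free_nospike_means: bool = False,
    final_prob: float = 0.01,
) -> MPHModel:
    """Switching model with ``n`` M-states and no X/R states.

    ``n = 1`` gives the minimal matching model (the LNP-equivalent
    architecture when covariances are shared).  Free parameters: the
    spike-conditioned means (one receptive field per state), the spike
    marginals, and the transitions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d = embedding.dim
    cov, cmode = _resolve_cov(d, data_cov, cov_mode)
    zero = np.zeros(d)
    states = []
    for i in range(n):
        states.append(
            StateSpec(
                kind="M",
                label=f"M{i}",
                emission=MixedEmission(
                    response_marginal=DiscreteEmission(
                        np.array([1.0 - spike_rate, spike_rate])
                    ),
                    conditional_stimulus=[
                        _fixed_gaussian(
                            zero,
                            cov,
                            cmode,
                            "free" if free_nospike_means else "fixed_zero",
                        ),
                        GaussianMixtureEmission(
                            weights=np.array([1.0]),
                            means=zero[None, :].copy(),
                            covariances=cov[None, :, :],
                            covariance_mode=cmode,
                            mean_mode="free",
                        ),
                    ],
                ),
            )
        )
    transitions = np.full((n, n), (1.0 - final_prob) / n)
    initial = np.full(n, 1.0 / n)
    final = np.full(n, final_prob)
    return MPHModel(
        states=states,
        transitions=transitions,
        initial=initial,
        final=final,
        band_width=0,
        embedding=embedding,
    )
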