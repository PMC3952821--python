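"""Readers and writers for data, model, and result files.

Stimulus-response data live in HDF5 (datasets ``stimulus`` [channels x T]
and ``response`` [T], with a mandatory ``bin_width`` attribute in seconds)
or, for small cases, in CSV (one row per channel).  Models are stored as a
single HDF5 file: a JSON header attribute captures the structure (state
kinds, labels, constraint flags, band width, embedding), and numeric
parameters live in datasets, so a round trip is bit-exact.  Results go to
CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .alignment import AlignmentKernel, HiddenPath
from .model import (
    DiscreteEmission,
    GaussianMixtureEmission,
    MixedEmission,
    MPHModel,
    StateSpec,
    StimulusEmbeddingSpec,
)

__all__ = [
    "save_pair_hdf5",
    "load_pair_hdf5",
    "read_spectrogram_csv",
    "save_model",
    "load_model",
    "write_kernel_csv",
    "write_path_csv",
    "write_predictions_csv",
    "write_metrics_json",
]


# ---------------------------------------------------------------------------
# stimulus / response data
# ---------------------------------------------------------------------------


def save_pair_hdf5(
    path, stimulus: np.ndarray, response: np.ndarray, bin_width: float
) -> None:
    """Write a raw ``channels x T`` stimulus and its binned response."""
    stimulus = np.atleast_2d(np.asarray(stimulus, dtype=float))
    response = np.asarray(response)
    if not np.issubdtype(response.dtype, np.integer):
        raise ValueError("response must be integer-valued")
    with h5py.File(path, "w") as f:
        f.create_dataset("stimulus", data=stimulus)
        f.create_dataset("response", data=response.astype(np.int64))
        f.attrs["bin_width"] = float(bin_width)


def load_pair_hdf5(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read (stimulus [channels x T], response [T], bin_width) with checks."""
    with h5py.File(path, "r") as f:
        for name in ("stimulus", "response"):
            if name not in f:
                raise ValueError(f"{path}: missing dataset {name!r}")
        if "bin_width" not in f.attrs:
            raise ValueError(f"{path}: missing mandatory attribute 'bin_width'")
        stimulus = np.asarray(f["stimulus"], dtype=float)
        response = np.asarray(f["response"])
        bin_width = float(f.attrs["bin_width"])
    if stimulus.ndim != 2:
        raise ValueError(f"{path}: stimulus must be 2-D (channels x time)")
    if response.ndim != 1:
        raise ValueError(f"{path}: response must be 1-D")
    if not np.issubdtype(response.dtype, np.integer):
        raise ValueError(f"{path}: response must be integer-valued")
    return stimulus, response.astype(np.int64), bin_width


def read_spectrogram_csv(path) -> np.ndarray:
    """Read a ``channels x time`` stimulus matrix from CSV, strictly numeric."""
    df = pd.read_csv(path, header=None)
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr) & df.notna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"{path}: non-numeric value at row {r}, column {c}")
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValueError(f"{path}: missing value at row {r}, column {c}")
    return arr


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def _gmm_header(g: GaussianMixtureEmission) -> dict:
    return {
        "type": "gmm",
        "n_components": int(g.n_components),
        "covariance_mode": g.covariance_mode,
        "mean_mode": g.mean_mode,
    }


def _write_gmm(grp: h5py.Group, name: str, g: GaussianMixtureEmission) -> None:
    grp.create_dataset(f"{name}_weights", data=g.weights)
    grp.create_dataset(f"{name}_means", data=g.means)
    grp.create_dataset(f"{name}_covs", data=g.covariances)


def _read_gmm(grp: h5py.Group, name: str, hdr: dict) -> GaussianMixtureEmission:
    return GaussianMixtureEmission(
        weights=np.asarray(grp[f"{name}_weights"]),
        means=np.asarray(grp[f"{name}_means"]),
        covariances=np.asarray(grp[f"{name}_covs"]),
        covariance_mode=hdr["covariance_mode"],
        mean_mode=hdr["mean_mode"],
    )


def save_model(path, model: MPHModel) -> None:
    """Serialize an MPH to HDF5 (JSON structure header + numeric datasets)."""
    header: dict = {"format": "mphmm-model", "version": 1, "states": []}
    header["band_width"] = int(model.band_width)
    if model.embedding is not None:
        e = model.embedding
        header["embedding"] = {
            "window_length": e.window_length,
            "window_offset": e.window_offset,
            "channels": e.channels,
        }
    header["has_lag_bounds"] = model.lag_bounds is not None
    with h5py.File(path, "w") as f:
        f.create_dataset("transitions", data=model.transitions)
        f.create_dataset("initial", data=model.initial)
        f.create_dataset("final", data=model.final)
        if model.lag_bounds is not None:
            f.create_dataset("lag_bounds", data=model.lag_bounds)
        for k, st in enumerate(model.states):
            shdr: dict = {"kind": st.kind, "label": st.label}
            if st.kind == "X":
                shdr["emission"] = _gmm_header(st.emission)
                _write_gmm(f, f"state_{k}", st.emission)
            elif st.kind == "R":
                shdr["emission"] = {"type": "discrete", "frozen": bool(st.emission.frozen)}
                f.create_dataset(f"state_{k}_probs", data=st.emission.probs)
            else:
                em = st.emission
                shdr["emission"] = {
                    "type": "mixed",
                    "marginal_frozen": bool(em.response_marginal.frozen),
                    "conditionals": [_gmm_header(g) for g in em.conditional_stimulus],
                }
                f.create_dataset(f"state_{k}_probs", data=em.response_marginal.probs)
                for v, g in enumerate(em.conditional_stimulus):
                    _write_gmm(f, f"state_{k}_r{v}", g)
            header["states"].append(shdr)
        f.attrs["header"] = json.dumps(header)


def load_model(path) -> MPHModel:
    """Inverse of :func:`save_model`; reproduces all parameters bit-exactly."""
    with h5py.File(path, "r") as f:
        if "header" not in f.attrs:
            raise ValueError(f"{path}: not an mphmm model file (missing header)")
        header = json.loads(f.attrs["header"])
        if header.get("format") != "mphmm-model":
            raise ValueError(f"{path}: not an mphmm model file")
        states: list[StateSpec] = []
        for k, shdr in enumerate(header["states"]):
            kind = shdr["kind"]
            if kind == "X":
                em = _read_gmm(f, f"state_{k}", shdr["emission"])
            elif kind == "R":
                em = DiscreteEmission(
                    np.asarray(f[f"state_{k}_probs"]), frozen=shdr["emission"]["frozen"]
                )
            else:
                conds = [
                    _read_gmm(f, f"state_{k}_r{v}", h)
                    for v, h in enumerate(shdr["emission"]["conditionals"])
                ]
                em = MixedEmission(
                    response_marginal=DiscreteEmission(
                        np.asarray(f[f"state_{k}_probs"]),
                        frozen=shdr["emission"]["marginal_frozen"],
                    ),
                    conditional_stimulus=conds,
                )
            states.append(StateSpec(kind=kind, emission=em, label=shdr["label"]))
        embedding = None
        if "embedding" in header:
            embedding = StimulusEmbeddingSpec(**header["embedding"])
        lag_bounds = (
            np.asarray(f["lag_bounds"]) if header.get("has_lag_bounds") else None
        )
        return MPHModel(
            states=states,
            transitions=np.asarray(f["transitions"]),
            initial=np.asarray(f["initial"]),
            final=np.asarray(f["final"]),
            band_width=header["band_width"],
            embedding=embedding,
            lag_bounds=lag_bounds,
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_kernel_csv(path, kernel: AlignmentKernel) -> None:
    pd.DataFrame(
        {
            "lag_bins": kernel.lags,
            "lag_seconds": kernel.lags_seconds,
            "probability": kernel.probs,
        }
    ).to_csv(path, index=False)


def write_path_csv(path, hidden_path: HiddenPath, labels: list[str] | None = None) -> None:
    traj = hidden_path.trajectory[1:]
    rows = {
        "step": np.arange(len(hidden_path)),
        "state_index": hidden_path.states,
        "state_kind": hidden_path.kinds,
        "i": [p[0] for p in traj],
        "j": [p[1] for p in traj],
    }
    if labels is not None:
        rows["state_label"] = [labels[s] for s in hidden_path.states]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_predictions_csv(
    path,
    spike_prob: np.ndarray,
    bin_width: float,
    cascaded: np.ndarray | None = None,
) -> None:
    T = len(spike_prob)
    cols = {
        "bin": np.arange(T),
        "time_s": np.arange(T) * bin_width,
        "p_spike": spike_prob,
    }
    if cascaded is not None:
        cols["p_spike_cascaded"] = cascaded
    pd.DataFrame(cols).to_csv(path, index=False)


def write_metrics_json(path, metrics: dict) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
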