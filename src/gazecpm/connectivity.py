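"""Functional connectivity from node timecourses.

Per run: per-node linear detrend and within-run standardization, joint
regression of 16 nuisance confounds (6 motion parameters, their first
derivatives, global/CSF/white-matter signals, framewise displacement) plus
one indicator regressor per motion-spike volume (FD > 0.5 mm), then
pairwise Pearson correlation between retained nodes and Fisher's z
transform. Runs with more than 25% spike volumes are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend

__all__ = [
    "RunData",
    "ConnectivityMatrix",
    "flag_spikes",
    "exclude_run",
    "clean_timecourses",
    "connectivity",
    "edge_index",
    "vectorize_edges",
    "FD_SPIKE_THRESHOLD",
    "MAX_SPIKE_FRACTION",
    "FISHER_CLIP",
]

FD_SPIKE_THRESHOLD = 0.5  # mm
MAX_SPIKE_FRACTION = 0.25
FISHER_CLIP = 1e-7


@dataclass
class RunData:
    """One participant-run: timecourses (T x N), confounds (T x 16), label."""

    timecourses: np.ndarray
    confounds: pd.DataFrame
    run_label: str = "sweet"

    def __post_init__(self) -> None:
        self.timecourses = np.asarray(self.timecourses, dtype=float)
        if self.timecourses.shape[0] != len(self.confounds):
            raise ValueError("timecourses and confounds must have equal rows")
        if np.isnan(self.timecourses).any() or self.confounds.isna().any().any():
            raise ValueError("missing values in run data")

    @property
    def fd(self) -> np.ndarray:
        return self.confounds["framewise_displacement"].to_numpy(dtype=float)


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix over retained nodes."""

    z: np.ndarray
    node_ids: np.ndarray
    n_volumes_used: int

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def edges(self) -> np.ndarray:
        """Strict upper triangle, row-major (the package's fixed edge order)."""
        return vectorize_edges(self.z)


def flag_spikes(fd: np.ndarray, threshold: float = FD_SPIKE_THRESHOLD) -> np.ndarray:
    """Motion-spike flags: framewise displacement strictly above threshold."""
    fd = np.asarray(fd, dtype=float)
    if (fd < 0).any():
        raise ValueError("framewise displacement cannot be negative")
    return fd > threshold


def exclude_run(spike_flags: np.ndarray, max_fraction: float = MAX_SPIKE_FRACTION) -> bool:
    """True when the flagged fraction strictly exceeds ``max_fraction``."""
    flags = np.asarray(spike_flags, dtype=bool)
    return bool(np.count_nonzero(flags) / len(flags) > max_fraction)


def clean_timecourses(run: RunData, spike_flags: np.ndarray | None = None) -> np.ndarray:
    """Detrend, standardize, and regress out confounds and spike indicators.

    Each node series is linearly detrended and z-scored, then the 16
    confound columns plus one indicator column per flagged volume (and an
    intercept) are jointly regressed out. The indicator regressors
    annihilate the flagged rows exactly, which censors those volumes while
    keeping the row count intact. Residuals are returned without
    re-standardization.
    """
    flags = flag_spikes(run.fd) if spike_flags is None else np.asarray(spike_flags, bool)
    Y = detrend(run.timecourses, axis=0, type="linear")
    sd = Y.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant node timecourse(s) at index {bad.tolist()}")
    Y = (Y - Y.mean(axis=0)) / sd

    T = Y.shape[0]
    conf = run.confounds.to_numpy(dtype=float)
    spikes_idx = np.flatnonzero(flags)
    indicators = np.zeros((T, len(spikes_idx)))
    indicators[spikes_idx, np.arange(len(spikes_idx))] = 1.0
    D = np.column_stack([np.ones(T), conf, indicators])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        warnings.warn("confound design is rank-deficient; using least-norm projection", stacklevel=2)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    resid[spikes_idx] = 0.0  # exact annihilation (removes lstsq round-off)
    return resid


def connectivity(
    clean: np.ndarray,
    drop_nodes: np.ndarray | list[int] | tuple[int, ...] = (),
    node_ids: np.ndarray | None = None,
    n_volumes_used: int | None = None,
    clip: float = FISHER_CLIP,
) -> ConnectivityMatrix:
    """Pairwise Fisher-z connectivity over retained nodes.

    ``drop_nodes`` removes nodes (e.g., cerebellar nodes without adequate
    coverage) before correlation. Correlations are clipped to
    ``1 - clip`` in absolute value so degenerate (duplicate) node pairs
    keep a finite z while preserving ordering.
    """
    clean = np.asarray(clean, dtype=float)
    N = clean.shape[1]
    ids = np.arange(N) if node_ids is None else np.asarray(node_ids)
    keep = np.setdiff1d(np.arange(N), np.asarray(drop_nodes, dtype=int))
    X = clean[:, keep]
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = ids[keep][sd == 0]
        raise ValueError(f"zero-variance node(s) after cleaning: {bad.tolist()}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1 + clip, 1 - clip)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        z=z,
        node_ids=ids[keep],
        n_volumes_used=int(clean.shape[0] if n_volumes_used is None else n_volumes_used),
    )


def edge_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed edge order: strict upper triangle, row-major, 0-based nodes."""
    return np.triu_indices(n_nodes, k=1)


def vectorize_edges(z: np.ndarray) -> np.ndarray:
    """Edge vector of a symmetric matrix in the fixed edge order."""
    iu, ju = edge_index(z.shape[0])
    return z[iu, ju]
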