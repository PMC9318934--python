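"""Displacement matrices and dynamic cross-correlation (DCC).

The displacement matrix D is m frames x p residues. In the default scalar
mode, entry D[j, i] is the Euclidean distance moved by residue i between
frame j-1 and frame j (the trajectory's reference structure acts as the
predecessor of frame 0). The DCC matrix is then the Pearson correlation of
the two length-m scalar series for each residue pair.

A vector mode is also provided: D stores the displacement vectors
Δr_i(t) themselves and DCC(i, j) = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>),
the classic normalized cross-correlation (no mean-centring). The two modes
differ; scalar-Pearson is the default.

High DCC blocks mark groups of residues moving in concert ("dynamical
domains"); values near zero mark independent motion. Residues with a
degenerate (zero-variance) displacement series yield flagged NaN entries,
excluded from averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "DisplacementMatrix",
    "DCCMatrix",
    "displacement_matrix",
    "dcc_matrix",
    "average_dcc",
    "submatrix",
    "partition_from_dcc",
    "block_mean_dcc",
]


@dataclass
class DisplacementMatrix:
    """Per-frame residue displacements of one trajectory."""

    values: np.ndarray          # (m, p) scalar or (m, p, 3) vector
    mode: str                   # "scalar" | "vector"
    residue_keys: list[str]
    seq_indices: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_residues(self) -> int:
        return self.values.shape[1]


@dataclass
class DCCMatrix:
    """p x p residue-residue motion correlation matrix."""

    values: np.ndarray
    mode: str
    residue_keys: list[str]
    seq_indices: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def displacement_matrix(traj: Trajectory, mode: str = "scalar") -> DisplacementMatrix:
    """Build D from a trajectory.

    Scalar mode: D[j, i] = ||r_i(t_j) − r_i(t_{j−1})||, with the reference
    frame standing in for t_{−1}. Vector mode stores the difference
    vectors themselves.
    """
    if mode not in ("scalar", "vector"):
        raise ValueError("mode must be 'scalar' or 'vector'")
    if len(traj) < 2:
        raise ValueError("need at least 2 frames")
    coords = traj.coord_stack()                       # (m, p, 3)
    prev = np.concatenate([traj.reference.coords[None], coords[:-1]])
    diff = coords - prev                              # (m, p, 3)
    if mode == "scalar":
        values = np.linalg.norm(diff, axis=2)
    else:
        values = diff
    return DisplacementMatrix(
        values=values,
        mode=mode,
        residue_keys=traj.reference.keys,
        seq_indices=traj.reference.seq_indices,
    )


def dcc_matrix(disp: DisplacementMatrix) -> DCCMatrix:
    """Residue-pair motion correlation from a displacement matrix.

    Scalar mode: Pearson correlation of the per-residue scalar series.
    Vector mode: <Δr_i·Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>). Zero-variance
    (scalar) or zero-norm (vector) series give NaN rows/columns.
    """
    if disp.n_frames < 3:
        raise ValueError("need at least 3 frames for correlations")
    if disp.mode == "scalar":
        D = disp.values
        sd = D.std(axis=0)
        degenerate = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(D, rowvar=False)
        C[degenerate, :] = np.nan
        C[:, degenerate] = np.nan
    else:
        V = disp.values                               # (m, p, 3)
        dots = np.einsum("mik,mjk->ij", V, V) / V.shape[0]
        norms = np.einsum("mik,mik->i", V, V) / V.shape[0]
        degenerate = norms == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = dots / np.sqrt(np.outer(norms, norms))
        C[degenerate, :] = np.nan
        C[:, degenerate] = np.nan
    if degenerate.any():
        logger.warning("%d residues with degenerate displacement series", degenerate.sum())
    C = (C + C.T) / 2.0
    idx = np.where(~degenerate)[0]
    C[idx, idx] = 1.0
    return DCCMatrix(C, disp.mode, list(disp.residue_keys), disp.seq_indices.copy())


def average_dcc(dcc: DCCMatrix) -> float:
    """Mean over off-diagonal, non-missing entries (unordered pairs)."""
    iu = np.triu_indices(dcc.n_residues, k=1)
    vals = dcc.values[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("all off-diagonal entries are missing")
    return float(vals.mean())


def submatrix(dcc: DCCMatrix, residue_range: tuple[int, int]) -> DCCMatrix:
    """Principal submatrix over residues with seq_index in [lo, hi]."""
    lo, hi = residue_range
    mask = (dcc.seq_indices >= lo) & (dcc.seq_indices <= hi)
    if not mask.any():
        raise ValueError(f"no residues in range {residue_range}")
    idx = np.where(mask)[0]
    return DCCMatrix(
        values=dcc.values[np.ix_(idx, idx)].copy(),
        mode=dcc.mode,
        residue_keys=[dcc.residue_keys[i] for i in idx],
        seq_indices=dcc.seq_indices[idx].copy(),
    )


def partition_from_dcc(dcc: DCCMatrix, n_blocks: int = 2, seed: int = 0) -> np.ndarray:
    """Assign residues to dynamical blocks by spectral partitioning.

    K-means (k = n_blocks) on the rows of the leading-eigenvector embedding
    of the DCC matrix (NaN entries treated as 0). Returns integer labels.
    """
    from scipy.cluster.vq import kmeans2

    C = np.nan_to_num(dcc.values, nan=0.0)
    lam, vec = np.linalg.eigh(C)
    emb = vec[:, -n_blocks:] * np.sqrt(np.abs(lam[-n_blocks:]))
    _, labels = kmeans2(emb, n_blocks, minit="++", seed=seed)
    return labels


def block_mean_dcc(dcc: DCCMatrix, membership: np.ndarray) -> tuple[float, float]:
    """(within-block, between-block) mean off-diagonal DCC."""
    membership = np.asarray(membership)
    iu, ju = np.triu_indices(dcc.n_residues, k=1)
    vals = dcc.values[iu, ju]
    same = membership[iu] == membership[ju]
    ok = ~np.isnan(vals)
    return float(vals[same & ok].mean()), float(vals[~same & ok].mean())
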