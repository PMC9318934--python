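"""Multivariate statistics of per-frame descriptor time series.

Each trajectory frame is reduced to one row of global descriptors — the
topology block (adeg, asp, abtw, aclose, acc, E plus the mixing
coefficients DBA, HBAKD, Dy, H) and the structure block (RG, RGh, RGp,
rho, eps, AS, MFD, corrHBKD) — with frame time t as an extra variable.
Three analyses are run on that table:

1. a pairwise-complete Pearson correlation map over all variables;
2. block canonical correlation analysis between X1 = {t},
   X2 = {adeg, asp, abtw, aclose, acc, E} and
   X3 = {RG, RGh, RGp, rho, eps, AS, MFD}, reporting the first (largest)
   canonical correlation per block pair — for the singleton time block
   this reduces to the multiple correlation of t with the other block;
3. PCA on the standardized variables (correlation-matrix PCA), with
   loadings reported as the Pearson correlation between each variable and
   each component score and only |loading| > 0.5 flagged as relevant.

The model/results pair :class:`TrajectoryMVA` / :class:`MVAResults` wraps
the three stages behind a single ``fit()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .descriptors import StructConfig, compute_structural_descriptors
from .network import build_pcn, network_summary, node_descriptors
from .structure_io import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSpec",
    "PCAResult",
    "MVAResults",
    "TrajectoryMVA",
    "descriptor_timeseries",
    "pearson_map",
    "first_canonical_correlation",
    "canonical_best_scores",
    "pca_loadings",
    "TABLE_VARIABLES",
]

#: Column order of the descriptor table (time first).
TABLE_VARIABLES = [
    "t",
    "DBA", "Dy", "H", "HBAKD", "abtw", "acc", "adeg", "asp", "aclose", "E",
    "RG", "RGh", "RGp", "corrHBKD", "rho", "MFD", "eps", "AS",
]


@dataclass
class BlockSpec:
    """Variable blocks for the canonical correlation stage."""

    X1: list[str] = field(default_factory=lambda: ["t"])
    X2: list[str] = field(default_factory=lambda: ["adeg", "asp", "abtw", "aclose", "acc", "E"])
    X3: list[str] = field(default_factory=lambda: ["RG", "RGh", "RGp", "rho", "eps", "AS", "MFD"])

    def validate(self, columns) -> None:
        names = [self.X1, self.X2, self.X3]
        flat = [v for blk in names for v in blk]
        if len(set(flat)) != len(flat):
            raise ValueError("blocks must be disjoint")
        missing = set(flat) - set(columns)
        if missing:
            raise ValueError(f"block variables missing from table: {sorted(missing)}")

    def items(self):
        return [("X1", self.X1), ("X2", self.X2), ("X3", self.X3)]


def descriptor_timeseries(
    traj: Trajectory,
    r_min: float = 4.0,
    r_max: float = 8.0,
    struct_config: StructConfig | None = None,
) -> pd.DataFrame:
    """One row of global descriptors per frame, time-ordered.

    Frames whose descriptor computation fails are kept as NaN rows with a
    logged cause, never silently dropped.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames")
    cfg = struct_config or StructConfig()
    rows = []
    for fr in traj.frames:
        row: dict[str, float] = {"t": float(fr.frame_index)}
        try:
            net = build_pcn(fr, r_min, r_max)
            row.update(network_summary(net, node_descriptors(net)).as_dict())
            row.update(compute_structural_descriptors(fr, cfg).as_dict())
        except Exception as exc:
            logger.warning("frame %d failed: %s", fr.frame_index, exc)
        rows.append(row)
    df = pd.DataFrame(rows, columns=TABLE_VARIABLES)
    return df


def pearson_map(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix; unit diagonal.

    Constant columns yield flagged NaN entries.
    """
    corr = table.corr(method="pearson", min_periods=3)
    return corr


def _block_matrix(table: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = table[cols].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    return X[ok]


def first_canonical_correlation(
    X: np.ndarray, Y: np.ndarray, ridge: float = 1e-8
) -> float:
    """First canonical correlation between two column blocks.

    Computed as the largest singular value of the whitened cross-covariance
    Sxx^{-1/2} Sxy Syy^{-1/2}; a small ridge stabilizes near-collinear
    blocks. Constant columns are dropped. Result clipped to [0, 1].
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n or n < max(X.shape[1], Y.shape[1]) + 2:
        raise ValueError("too few rows for the block sizes")
    X = X[:, X.std(axis=0) > 0]
    Y = Y[:, Y.std(axis=0) > 0]
    if X.shape[1] == 0 or Y.shape[1] == 0:
        return float("nan")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    Sxx += ridge * np.eye(Sxx.shape[0]) * max(np.trace(Sxx) / Sxx.shape[0], 1.0)
    Syy += ridge * np.eye(Syy.shape[0]) * max(np.trace(Syy) / Syy.shape[0], 1.0)
    Kx = linalg.inv(linalg.sqrtm(Sxx).real)
    Ky = linalg.inv(linalg.sqrtm(Syy).real)
    s = linalg.svd(Kx @ Sxy @ Ky, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def canonical_best_scores(
    table: pd.DataFrame, blocks: BlockSpec | None = None, ridge: float = 1e-8
) -> pd.DataFrame:
    """3x3 matrix of first canonical correlations between variable blocks."""
    blocks = blocks or BlockSpec()
    blocks.validate(table.columns)
    names = [name for name, _ in blocks.items()]
    out = pd.DataFrame(np.eye(3), index=names, columns=names)
    items = blocks.items()
    for a in range(3):
        for b in range(a + 1, 3):
            cols = items[a][1] + items[b][1]
            sub = table[cols].dropna()
            score = first_canonical_correlation(
                sub[items[a][1]].to_numpy(), sub[items[b][1]].to_numpy(), ridge
            )
            out.iloc[a, b] = out.iloc[b, a] = score
    return out


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the descriptor table."""

    variance_fractions: np.ndarray       # per retained component
    eigenvalues: np.ndarray              # all, descending; sums to n vars
    loadings: pd.DataFrame               # variables x components (correlations)
    reported_loadings: dict[str, dict[str, float]]
    dropped: list[str]                   # constant columns excluded


def pca_loadings(
    table: pd.DataFrame,
    n_components: int = 2,
    loading_threshold: float = 0.5,
) -> PCAResult:
    """PCA on standardized columns with loadings as variable-score correlations.

    Component signs are fixed deterministically: the loading of t is made
    non-positive whenever t loads on the component; otherwise the variable
    with the largest |loading| is made positive.
    """
    data = table.dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    cols = list(data.columns)
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        logger.warning("constant columns excluded from PCA: %s", dropped)
    cols = [c for c, k in zip(cols, keep) if k]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    R = np.atleast_2d(np.corrcoef(Z, rowvar=False))
    lam, vec = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam = np.clip(lam, 0.0, None)
    n_components = min(n_components, len(cols))
    scores = Z @ vec[:, :n_components]
    load = np.empty((len(cols), n_components))
    for k in range(n_components):
        s = scores[:, k]
        s_sd = s.std(ddof=1)
        load[:, k] = 0.0 if s_sd == 0 else (Z * (s - s.mean())[:, None]).sum(0) / (
            (len(s) - 1) * s_sd
        )
    # deterministic sign convention
    for k in range(n_components):
        if "t" in cols and abs(load[cols.index("t"), k]) > 1e-12:
            flip = load[cols.index("t"), k] > 0
        else:
            flip = load[np.argmax(np.abs(load[:, k])), k] < 0
        if flip:
            load[:, k] = -load[:, k]
            vec[:, k] = -vec[:, k]
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    loadings = pd.DataFrame(load, index=cols, columns=comp_names)
    reported = {
        pc: {
            var: float(loadings.loc[var, pc])
            for var in cols
            if abs(loadings.loc[var, pc]) > loading_threshold
        }
        for pc in comp_names
    }
    return PCAResult(
        variance_fractions=lam[:n_components] / len(cols),
        eigenvalues=lam,
        loadings=loadings,
        reported_loadings=reported,
        dropped=dropped,
    )


@dataclass
class MVAResults:
    """Fitted multivariate analysis of one descriptor table."""

    table: pd.DataFrame
    pearson: pd.DataFrame
    cca_best: pd.DataFrame
    pca: PCAResult
    blocks: BlockSpec

    def summary(self) -> str:
        lines = ["Multivariate analysis of frame descriptors",
                 "=" * 44,
                 f"frames: {len(self.table)}   variables: {self.table.shape[1]}",
                 "",
                 "First canonical correlations between blocks:"]
        lines.append(self.cca_best.round(3).to_string())
        lines.append("")
        vf = ", ".join(
            f"PC{k + 1} {100 * f:.1f}%" for k, f in enumerate(self.pca.variance_fractions)
        )
        lines.append(f"PCA variance fractions: {vf}")
        for pc, loads in self.pca.reported_loadings.items():
            if loads:
                body = ", ".join(f"{v} = {x:.2f}" for v, x in sorted(loads.items()))
                lines.append(f"  {pc} loadings (|l| > 0.5): {body}")
        drift = self.pearson.loc["t"].drop("t").abs().idxmax() if "t" in self.pearson else None
        if drift is not None and np.isfinite(self.pearson.loc["t", drift]):
            lines.append(
                f"strongest time trend: corr(t, {drift}) = {self.pearson.loc['t', drift]:.2f}"
            )
        return "\n".join(lines)


class TrajectoryMVA:
    """Multivariate model of a trajectory's global-descriptor dynamics.

    Build either from a precomputed descriptor table
    (``TrajectoryMVA(table)``) or directly from a trajectory
    (:meth:`from_trajectory`), then :meth:`fit`.
    """

    def __init__(self, table: pd.DataFrame, blocks: BlockSpec | None = None):
        if "t" not in table.columns:
            raise ValueError("table must contain a 't' column")
        t = table["t"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        if len(set(table.columns)) != table.shape[1]:
            raise ValueError("duplicated column names")
        self.table = table.reset_index(drop=True)
        self.blocks = blocks or BlockSpec()
        self.blocks.validate(table.columns)

    @classmethod
    def from_trajectory(
        cls,
        traj: Trajectory,
        r_min: float = 4.0,
        r_max: float = 8.0,
        struct_config: StructConfig | None = None,
        blocks: BlockSpec | None = None,
    ) -> "TrajectoryMVA":
        return cls(descriptor_timeseries(traj, r_min, r_max, struct_config), blocks)

    def fit(
        self,
        n_components: int = 2,
        loading_threshold: float = 0.5,
        ridge: float = 1e-8,
    ) -> MVAResults:
        return MVAResults(
            table=self.table,
            pearson=pearson_map(self.table),
            cca_best=canonical_best_scores(self.table, self.blocks, ridge),
            pca=pca_loadings(self.table, n_components, loading_threshold),
            blocks=self.blocks,
        )
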