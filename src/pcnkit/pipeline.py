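"""End-to-end orchestration: structures in, reports and tables out.

Two entry points mirror the two halves of the analysis:

- :func:`run_compare` takes an active and an inactive frame and emits the
  per-form network and structure summaries, the Jaccard contact overlap,
  the active-minus-inactive difference map at the |Δk| and |Δbtw|
  thresholds, and the high-degree / high-betweenness node selections.
- :func:`run_trajectory` takes a trajectory and emits the per-frame
  descriptor table, the DCC matrix with its off-diagonal average, and the
  multivariate stage (Pearson map, block CCA, PCA).

All numeric outputs are delimited text or JSON written with fixed float
formatting, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import StructConfig, StructuralDescriptors, compute_structural_descriptors
from .motion import DCCMatrix, average_dcc, dcc_matrix, displacement_matrix
from .mva import BlockSpec, MVAResults, TrajectoryMVA, descriptor_timeseries
from .network import (
    ContactNetwork,
    DifferenceMap,
    NetworkSummary,
    NodeDescriptors,
    build_pcn,
    difference_map,
    jaccard_similarity,
    network_summary,
    node_descriptors,
    threshold_nodes,
)
from .structure_io import StructureFrame, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ComparisonReport", "TrajectoryReport", "run_compare", "run_trajectory"]

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Serializable settings for one analysis run."""

    r_min: float = 4.0
    r_max: float = 8.0
    theta_k: float = 1.0        # |Δk| selection threshold
    theta_btw: float = 500.0    # |Δbtw| selection threshold
    k_high: float = 10.0        # high-degree node selection
    btw_high: float = 1200.0    # high-betweenness node selection
    dcc_mode: str = "scalar"
    seed: int = 0
    struct: StructConfig = field(default_factory=StructConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def _node_table(desc: NodeDescriptors) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": desc.node_labels,
            "k": desc.k,
            "cc": desc.cc,
            "btw": desc.btw,
            "close": desc.close,
        }
    )


def _write_edges(net: ContactNetwork, path: Path) -> None:
    lines = [
        f"{net.node_labels[i]}\t{net.node_labels[j]}"
        for i, j in net.edge_index_pairs()
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class ComparisonReport:
    """Active-vs-inactive single-frame comparison."""

    net_summary_active: NetworkSummary
    net_summary_inactive: NetworkSummary
    struct_active: StructuralDescriptors
    struct_inactive: StructuralDescriptors
    jaccard: float | None
    diff: DifferenceMap | None
    high_k: dict[str, set]
    high_btw: dict[str, set]
    config: RunConfig

    def global_table(self) -> pd.DataFrame:
        """Side-by-side global-property table for the two forms."""
        rows = {}
        for form, ns, sd in (
            ("inactive", self.net_summary_inactive, self.struct_inactive),
            ("active", self.net_summary_active, self.struct_active),
        ):
            rows[form] = {
                "MFD": sd.MFD, "RG": sd.RG, "eps": sd.eps, "AS": sd.AS,
                "corrHb": sd.corrHBKD, "adeg": ns.adeg, "abtw": ns.abtw,
                "asp": ns.asp, "E": ns.E,
            }
        df = pd.DataFrame(rows)
        df.loc["Jacc"] = [self.jaccard, self.jaccard]
        return df

    def summary(self) -> str:
        lines = ["Active vs inactive comparison", "=" * 32]
        lines.append(self.global_table().round(3).to_string())
        if self.jaccard is not None:
            lines.append(f"contact rewiring: 1 - Jacc = {1 - self.jaccard:.3f}")
        if self.diff is not None:
            lines.append(
                f"|Δk| > {self.diff.theta_k:g}: {len(self.diff.selected_k)} residues; "
                f"|Δbtw| > {self.diff.theta_btw:g}: {len(self.diff.selected_btw)} residues"
            )
        return "\n".join(lines)


def run_compare(
    active: StructureFrame,
    inactive: StructureFrame,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> ComparisonReport:
    """Full two-form comparison; optionally writes all artifacts."""
    cfg = config or RunConfig()
    nets, descs, summaries, structs = {}, {}, {}, {}
    for name, frame in (("active", active), ("inactive", inactive)):
        net = build_pcn(frame, cfg.r_min, cfg.r_max)
        desc = node_descriptors(net)
        nets[name] = net
        descs[name] = desc
        summaries[name] = network_summary(net, desc)
        structs[name] = compute_structural_descriptors(frame, cfg.struct)

    aligned = active.keys == inactive.keys
    if aligned:
        jacc = jaccard_similarity(nets["active"], nets["inactive"])
        diff = difference_map(descs["active"], descs["inactive"], cfg.theta_k, cfg.theta_btw)
    else:
        logger.warning("residue sets differ; skipping Jaccard and difference map")
        jacc, diff = None, None

    report = ComparisonReport(
        net_summary_active=summaries["active"],
        net_summary_inactive=summaries["inactive"],
        struct_active=structs["active"],
        struct_inactive=structs["inactive"],
        jaccard=jacc,
        diff=diff,
        high_k={
            name: threshold_nodes(descs[name].k.astype(float), cfg.k_high, descs[name].node_labels)
            for name in ("active", "inactive")
        },
        high_btw={
            name: threshold_nodes(descs[name].btw, cfg.btw_high, descs[name].node_labels)
            for name in ("active", "inactive")
        },
        config=cfg,
    )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.write(out / "config.json")
        for name in ("active", "inactive"):
            _node_table(descs[name]).to_csv(
                out / f"nodes_{name}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
            _write_edges(nets[name], out / f"edges_{name}.tsv")
            _write_json(
                {**summaries[name].as_dict(), **structs[name].as_dict()},
                out / f"summary_{name}.json",
            )
        payload = {
            "jaccard": jacc,
            "high_k": {k: sorted(v) for k, v in report.high_k.items()},
            "high_btw": {k: sorted(v) for k, v in report.high_btw.items()},
        }
        if diff is not None:
            pd.DataFrame(
                {"residue": diff.node_labels, "delta_k": diff.delta_k, "delta_btw": diff.delta_btw}
            ).to_csv(out / "difference_map.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            payload["selected_k"] = sorted(diff.selected_k)
            payload["selected_btw"] = sorted(diff.selected_btw)
        _write_json(payload, out / "comparison.json")
    return report


@dataclass
class TrajectoryReport:
    """Full trajectory analysis: descriptor table, DCC and MVA stages."""

    table: pd.DataFrame
    dcc: DCCMatrix | None
    dcc_average: float | None
    mva: MVAResults | None
    config: RunConfig

    def summary(self) -> str:
        lines = [f"Trajectory analysis over {len(self.table)} frames", "=" * 40]
        if self.dcc_average is not None:
            lines.append(f"average off-diagonal DCC: {self.dcc_average:.3f}")
        if self.mva is not None:
            lines.append(self.mva.summary())
        return "\n".join(lines)


def run_trajectory(
    traj: Trajectory,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    blocks: BlockSpec | None = None,
) -> TrajectoryReport:
    """Descriptor table + DCC + multivariate stage for one trajectory.

    The DCC stage needs at least 3 frames and the multivariate stage at
    least 3 usable rows; stages whose preconditions fail are skipped with
    a logged warning while the rest of the run proceeds. The run aborts
    only when more than 20% of frames fail descriptor computation.
    """
    cfg = config or RunConfig()
    table = _timeseries_lenient(traj, cfg)

    usable = (~table.drop(columns="t").isna().all(axis=1)).sum()
    if usable < 0.8 * len(traj):
        raise RuntimeError(f"only {usable}/{len(traj)} frames usable (<80%)")

    dcc = dcc_avg = None
    if len(traj) >= 3:
        dcc = dcc_matrix(displacement_matrix(traj, cfg.dcc_mode))
        dcc_avg = average_dcc(dcc)
    else:
        logger.warning("fewer than 3 frames; DCC stage skipped")

    mva = None
    if table.dropna().shape[0] >= 3:
        mva = TrajectoryMVA(table, blocks).fit()
    else:
        logger.warning("fewer than 3 complete rows; multivariate stage skipped")

    report = TrajectoryReport(table=table, dcc=dcc, dcc_average=dcc_avg, mva=mva, config=cfg)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.write(out / "config.json")
        table.to_csv(out / "descriptors.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        if dcc is not None:
            pd.DataFrame(dcc.values, index=dcc.residue_keys, columns=dcc.residue_keys).to_csv(
                out / "dcc.tsv", sep="\t", float_format=_FLOAT_FMT
            )
            n_missing = int(np.isnan(dcc.values).sum())
            _write_json(
                {
                    "average": dcc_avg,
                    "min": float(np.nanmin(dcc.values)),
                    "max": float(np.nanmax(dcc.values)),
                    "missing_entries": n_missing,
                    "mode": dcc.mode,
                },
                out / "dcc_summary.json",
            )
        if mva is not None:
            mva.pearson.to_csv(out / "pearson.tsv", sep="\t", float_format=_FLOAT_FMT)
            _write_json(
                {c: mva.cca_best[c].to_dict() for c in mva.cca_best.columns},
                out / "cca.json",
            )
            _write_json(
                {
                    "variance_fractions": mva.pca.variance_fractions,
                    "reported_loadings": mva.pca.reported_loadings,
                    "dropped_columns": mva.pca.dropped,
                },
                out / "pca.json",
            )
    return report


def _timeseries_lenient(traj: Trajectory, cfg: RunConfig) -> pd.DataFrame:
    """Descriptor table without the >=3-frame precondition (pipeline use)."""
    if len(traj) >= 3:
        return descriptor_timeseries(traj, cfg.r_min, cfg.r_max, cfg.struct)
    from .mva import TABLE_VARIABLES

    rows = []
    for fr in traj.frames:
        row: dict[str, float] = {"t": float(fr.frame_index)}
        try:
            net = build_pcn(fr, cfg.r_min, cfg.r_max)
            row.update(network_summary(net, node_descriptors(net)).as_dict())
            row.update(compute_structural_descriptors(fr, cfg.struct).as_dict())
        except Exception as exc:
            logger.warning("frame %d failed: %s", fr.frame_index, exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_VARIABLES)
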