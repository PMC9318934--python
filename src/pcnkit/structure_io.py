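"""Cα-level structure input/output.

Reads single- and multi-model PDB files down to one record per residue
(the Cα atom), annotates each residue with its average mass, Kyte-Doolittle
hydropathy and hydrophobic/polar class, and provides a lossless delimited
frame-table format used for synthetic fixtures and pipeline outputs.

Only canonical amino-acid residues with a Cα atom become records; hetero
records, ligands, waters and non-CA atoms are ignored. Altloc conflicts are
resolved to the highest-occupancy conformer. Residue order follows the
ATOM-record order of the source file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import (
    CANONICAL_RESIDUES,
    HYDROPHOBIC,
    KYTE_DOOLITTLE,
    POLAR,
    RESIDUE_MASS,
)

__all__ = [
    "ResidueRecord",
    "StructureFrame",
    "Trajectory",
    "assign_residue_annotations",
    "parse_pdb_ca",
    "write_frame_table",
    "read_frame_table",
    "write_trajectory_pdb",
]


class StructureError(ValueError):
    """Raised for malformed or unusable structural input."""


def assign_residue_annotations(
    res_name: str, extensions: dict[str, tuple[float, float]] | None = None
) -> tuple[float, float, str]:
    """Return ``(mass, kd_hydrophobicity, hp_class)`` for a 3-letter code.

    ``extensions`` may map non-canonical codes to ``(mass, kd)`` pairs.
    The class is hydrophobic iff the Kyte-Doolittle value is positive.
    """
    code = res_name.upper()
    if code in CANONICAL_RESIDUES:
        mass, kd = RESIDUE_MASS[code], KYTE_DOOLITTLE[code]
    elif extensions is not None and code in extensions:
        mass, kd = extensions[code]
    else:
        raise StructureError(f"unknown residue code {res_name!r}")
    return mass, kd, HYDROPHOBIC if kd > 0 else POLAR


@dataclass(frozen=True)
class ResidueRecord:
    """One residue, reduced to its Cα atom plus static annotations."""

    chain_id: str
    seq_index: int
    res_name: str
    ca_xyz: tuple[float, float, float]
    mass: float
    kd_hydrophobicity: float
    hp_class: str
    ins_code: str = ""

    @property
    def key(self) -> str:
        """Stable residue identifier, e.g. ``A:131`` (insertion code appended)."""
        return f"{self.chain_id}:{self.seq_index}{self.ins_code}"


@dataclass
class StructureFrame:
    """An ordered set of residues for one structural snapshot."""

    residues: list[ResidueRecord]
    frame_index: int = 0
    time_label: float = 0.0

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (chain, seq_index) residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.residues]

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([r.mass for r in self.residues], dtype=float)

    @property
    def kd_values(self) -> np.ndarray:
        return np.array([r.kd_hydrophobicity for r in self.residues], dtype=float)

    @property
    def hp_classes(self) -> np.ndarray:
        return np.array([r.hp_class for r in self.residues], dtype=object)

    @property
    def seq_indices(self) -> np.ndarray:
        return np.array([r.seq_index for r in self.residues], dtype=int)

    def with_coords(self, coords: np.ndarray, frame_index: int | None = None,
                    time_label: float | None = None) -> "StructureFrame":
        """Copy of this frame with replaced Cα coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.residues), 3):
            raise StructureError("coordinate array shape mismatch")
        res = [
            replace(r, ca_xyz=tuple(float(x) for x in xyz))
            for r, xyz in zip(self.residues, coords)
        ]
        return StructureFrame(
            res,
            self.frame_index if frame_index is None else frame_index,
            self.time_label if time_label is None else time_label,
        )


@dataclass
class Trajectory:
    """Time-ordered frames sharing one residue set, plus a reference frame.

    The reference frame is the input structure; it acts as the predecessor
    of frame 0 when per-frame displacements are computed.
    """

    frames: list[StructureFrame]
    reference: StructureFrame

    def __post_init__(self) -> None:
        ref_keys = self.reference.keys
        for fr in self.frames:
            if fr.keys != ref_keys:
                raise StructureError("frames differ in residue set or order")
        idx = [fr.frame_index for fr in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return len(self.reference)

    def coord_stack(self) -> np.ndarray:
        """(n_frames, n_residues, 3) coordinate array (reference excluded)."""
        return np.stack([fr.coords for fr in self.frames])


def _records_from_atom_array(atoms: struc.AtomArray) -> list[ResidueRecord]:
    records: list[ResidueRecord] = []
    for i in range(atoms.array_length()):
        if atoms.atom_name[i] != "CA" or bool(atoms.hetero[i]):
            continue
        res_name = str(atoms.res_name[i])
        if res_name not in CANONICAL_RESIDUES:
            continue  # non-amino-acid records are excluded from the network
        mass, kd, hp = assign_residue_annotations(res_name)
        ins = str(atoms.ins_code[i]).strip() if "ins_code" in atoms.get_annotation_categories() else ""
        records.append(
            ResidueRecord(
                chain_id=str(atoms.chain_id[i]),
                seq_index=int(atoms.res_id[i]),
                res_name=res_name,
                ca_xyz=tuple(float(x) for x in atoms.coord[i]),
                mass=mass,
                kd_hydrophobicity=kd,
                hp_class=hp,
                ins_code=ins,
            )
        )
    return records


def parse_pdb_ca(
    path: str | Path,
    model_policy: str = "first",
    chain_filter: str | Sequence[str] | None = None,
) -> StructureFrame | Trajectory:
    """Parse a PDB file down to Cα records.

    Parameters
    ----------
    path
        PDB file with at least one ATOM record carrying a CA atom.
    model_policy
        ``"first"`` returns a :class:`StructureFrame` from the first MODEL;
        ``"all"`` returns a :class:`Trajectory` with one frame per MODEL
        (the first model doubles as the reference structure).
    chain_filter
        Optional chain id (or ids) to restrict to; by default all protein
        chains are concatenated in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()

    if isinstance(chain_filter, str):
        chain_filter = [chain_filter]

    def one_model(m: int) -> list[ResidueRecord]:
        atoms = pdb.get_structure(model=m, altloc="occupancy", extra_fields=["occupancy"])
        recs = _records_from_atom_array(atoms)
        if chain_filter is not None:
            recs = [r for r in recs if r.chain_id in chain_filter]
        return recs

    first = one_model(1)
    if not first:
        raise StructureError(f"no Cα atoms found in {path}")
    if model_policy == "first":
        return StructureFrame(first, frame_index=0, time_label=0.0)

    frames = [StructureFrame(first, frame_index=0, time_label=0.0)]
    key0 = frames[0].keys
    for m in range(2, n_models + 1):
        recs = one_model(m)
        fr = StructureFrame(recs, frame_index=m - 1, time_label=float(m - 1))
        if fr.keys != key0:
            raise StructureError(f"model {m} residue set differs from model 1")
        frames.append(fr)
    return Trajectory(frames=frames, reference=frames[0])


_TABLE_COLUMNS = [
    "chain_id", "seq_index", "ins_code", "res_name",
    "x", "y", "z", "mass", "kd", "hp_class",
]


def write_frame_table(frame: StructureFrame, path: str | Path) -> None:
    """Write a frame as a TSV table, one row per residue (lossless)."""
    if len(frame) == 0:
        raise StructureError("refusing to write an empty frame")
    rows = [
        {
            "chain_id": r.chain_id,
            "seq_index": r.seq_index,
            "ins_code": r.ins_code,
            "res_name": r.res_name,
            "x": r.ca_xyz[0],
            "y": r.ca_xyz[1],
            "z": r.ca_xyz[2],
            "mass": r.mass,
            "kd": r.kd_hydrophobicity,
            "hp_class": r.hp_class,
        }
        for r in frame.residues
    ]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_frame_table(path: str | Path) -> StructureFrame:
    """Read a frame written by :func:`write_frame_table`."""
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"chain_id": str, "ins_code": str},
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise StructureError(f"malformed frame table: {exc}") from exc
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise StructureError(f"frame table missing columns {sorted(missing)}")
    for col in ("x", "y", "z", "mass", "kd"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise StructureError(f"non-numeric values in column {col!r}")
    records = [
        ResidueRecord(
            chain_id=str(row.chain_id),
            seq_index=int(row.seq_index),
            res_name=str(row.res_name),
            ca_xyz=(float(row.x), float(row.y), float(row.z)),
            mass=float(row.mass),
            kd_hydrophobicity=float(row.kd),
            hp_class=str(row.hp_class),
            ins_code="" if pd.isna(row.ins_code) else str(row.ins_code),
        )
        for row in df.itertuples()
    ]
    return StructureFrame(records)


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model, Cα-only PDB file."""
    ref = traj.reference
    n = len(ref)
    template = struc.AtomArray(n)
    template.chain_id = np.array([r.chain_id for r in ref.residues])
    template.res_id = np.array([r.seq_index for r in ref.residues])
    template.res_name = np.array([r.res_name for r in ref.residues])
    template.atom_name = np.full(n, "CA")
    template.element = np.full(n, "C")
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([template] * len(traj.frames))
    stack.coord = traj.coord_stack().astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
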