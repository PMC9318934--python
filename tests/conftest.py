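"""Shared fixtures: toy PDB text and small random graphs."""

from __future__ import annotations

import numpy as np
import pytest

from pcnkit.network import ContactNetwork


TOY_PDB = """\
ATOM      1  N   MET A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  MET A   1      11.000  10.000  10.000  1.00  0.00           C
ATOM      3  CA  GLY A   2      14.000  10.000  10.000  1.00  0.00           C
ATOM      4  CB  GLY A   2      14.500  11.000  10.000  1.00  0.00           C
ATOM      5  CA  ILE A   3      17.000  10.000  10.000  1.00  0.00           C
HETATM    6  CA  HOH A 101       5.000   5.000   5.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def toy_pdb_multimodel(tmp_path):
    body = "".join(
        line + "\n" for line in TOY_PDB.splitlines() if line.startswith(("ATOM", "HETATM"))
    )
    text = f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{body}ENDMDL\nEND\n"
    path = tmp_path / "toy_mm.pdb"
    path.write_text(text)
    return path


def net_from_edges(n: int, edges) -> ContactNetwork:
    A = np.zeros((n, n), dtype=int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return ContactNetwork(A, [f"A:{i + 1}" for i in range(n)])


def random_geometric_net(n: int, rng: np.random.Generator,
                         box: float = 4.0, radius: float = 1.2) -> ContactNetwork:
    """Random geometric graph: points in a box, edges below a radius."""
    pts = rng.uniform(0, box, size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    A = ((d > 0) & (d <= radius)).astype(int)
    np.fill_diagonal(A, 0)
    return ContactNetwork(A, [f"A:{i + 1}" for i in range(n)])
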