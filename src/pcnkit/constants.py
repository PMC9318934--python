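"""Residue-level constant tables.

Average residue masses (Da, monomer minus water, i.e. the mass a residue
contributes inside a chain) and the Kyte-Doolittle hydropathy scale for the
20 canonical amino acids. The hydrophobic/polar partition used throughout
the package is the sign of the Kyte-Doolittle value: KD > 0 is hydrophobic
(ALA, CYS, PHE, ILE, LEU, MET, VAL), everything else polar.
"""

from __future__ import annotations

#: Average residue (peptide-bonded) masses in Da.
RESIDUE_MASS: dict[str, float] = {
    "GLY": 57.0519,
    "ALA": 71.0788,
    "SER": 87.0782,
    "PRO": 97.1167,
    "VAL": 99.1326,
    "THR": 101.1051,
    "CYS": 103.1388,
    "LEU": 113.1594,
    "ILE": 113.1594,
    "ASN": 114.1038,
    "ASP": 115.0886,
    "GLN": 128.1307,
    "LYS": 128.1741,
    "GLU": 129.1155,
    "MET": 131.1926,
    "HIS": 137.1411,
    "PHE": 147.1766,
    "ARG": 156.1875,
    "TYR": 163.1760,
    "TRP": 186.2132,
}

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5,
    "VAL": 4.2,
    "LEU": 3.8,
    "PHE": 2.8,
    "CYS": 2.5,
    "MET": 1.9,
    "ALA": 1.8,
    "GLY": -0.4,
    "THR": -0.7,
    "SER": -0.8,
    "TRP": -0.9,
    "TYR": -1.3,
    "PRO": -1.6,
    "HIS": -3.2,
    "GLU": -3.5,
    "GLN": -3.5,
    "ASP": -3.5,
    "ASN": -3.5,
    "LYS": -3.9,
    "ARG": -4.5,
}

HYDROPHOBIC = "hydrophobic"
POLAR = "polar"

CANONICAL_RESIDUES = frozenset(RESIDUE_MASS)
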