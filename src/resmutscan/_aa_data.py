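"""Amino-acid reference tables shared across modules.

All tables are keyed by one-letter codes. Three-letter mappings follow PDB
naming; side-chain atom name lists follow PDB v3 heavy-atom conventions.
"""

from __future__ import annotations

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Heavy side-chain atoms, in graft order (outward from CB).
SIDECHAIN_ATOMS = {
    "A": ["CB"],
    "R": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "N": ["CB", "CG", "OD1", "ND2"],
    "D": ["CB", "CG", "OD1", "OD2"],
    "C": ["CB", "SG"],
    "Q": ["CB", "CG", "CD", "OE1", "NE2"],
    "E": ["CB", "CG", "CD", "OE1", "OE2"],
    "G": [],
    "H": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "I": ["CB", "CG1", "CG2", "CD1"],
    "L": ["CB", "CG", "CD1", "CD2"],
    "K": ["CB", "CG", "CD", "CE", "NZ"],
    "M": ["CB", "CG", "SD", "CE"],
    "F": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "P": ["CB", "CG", "CD"],
    "S": ["CB", "OG"],
    "T": ["CB", "OG1", "CG2"],
    "W": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "Y": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "V": ["CB", "CG1", "CG2"],
}

# Theoretical maximum accessible surface areas (A^2), Tien et al. 2013,
# used as RSA denominators.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Kyte-Doolittle hydropathy scale.
HYDROPATHY = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Residue volumes (A^3), Zamyatnin-style consensus values.
VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Formal charge signs at physiological pH used for the charge vector.
CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

# Van der Waals radii (A) by element for surface-area integration.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
VDW_DEFAULT = 1.70

HALOGENS = {"F", "CL", "BR", "I"}

# Aromatic ring atom names per residue type (TRP contributes two rings).
AROMATIC_RINGS = {
    "F": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "Y": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "H": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "W": [["CG", "CD1", "CD2", "NE1", "CE2"],
          ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
}

# Cationic side-chain atoms for pi-cation detection.
CATION_ATOMS = {"K": ["NZ"], "R": ["CZ"], "H": ["NE2"]}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PYRIMIDINES = {"C", "T"}
PURINES = {"A", "G"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))
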