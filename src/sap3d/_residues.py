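"""Canonical residue alphabets and per-residue physical constants.

The fixed residue order used throughout the package (feature vectors,
contact matrices) is the alphabetical one-letter order ACDEFGHIKLMNPQRSTVWY.
"""

from __future__ import annotations

import numpy as np

AA1: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA1)}
N_RESIDUE_TYPES: int = 20

AA3 = (
    "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
    "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR",
)
THREE_TO_ONE: dict[str, str] = dict(zip(AA3, AA1))
ONE_TO_THREE: dict[str, str] = dict(zip(AA1, AA3))

# Common chemically modified residues mapped to their canonical parent before
# any structural filtering; unmapped het groups are dropped with a warning.
MODIFIED_RESIDUES: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (treated as CYS for environment purposes)
    "CSO": "CYS",
    "CSD": "CYS",
    "OCS": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "HYP": "PRO",
    "MLY": "LYS",
    "KCX": "LYS",
    "PCA": "GLU",
    "FME": "MET",
    "MLZ": "LYS",
    "HIC": "HIS",
}

# Bondi-style van der Waals radii (angstrom) for elements found in protein
# heavy atoms; unknown elements fall back to the carbon radius with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
    "H": 1.20,
    "D": 1.20,
}
DEFAULT_VDW_RADIUS: float = 1.70

# Maximum attainable solvent accessible area per residue type (angstrom^2),
# Rost & Sander normalisation constants, used to express SASA as percent RSA.
MAX_ASA: dict[str, float] = {
    "A": 106.0, "C": 135.0, "D": 163.0, "E": 194.0, "F": 197.0,
    "G": 84.0, "H": 184.0, "I": 169.0, "K": 205.0, "L": 164.0,
    "M": 188.0, "N": 157.0, "P": 136.0, "Q": 198.0, "R": 248.0,
    "S": 130.0, "T": 142.0, "V": 142.0, "W": 227.0, "Y": 222.0,
}

MAX_ASA_ARRAY: np.ndarray = np.array([MAX_ASA[aa] for aa in AA1])


def is_canonical(code: str) -> bool:
    """True if *code* is one of the 20 canonical one-letter residue codes."""
    return len(code) == 1 and code in AA_INDEX
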