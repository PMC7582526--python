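"""Amino-acid property scales and physical constants.

Every sequence descriptor in this package starts from seven numeric scales
defined on the 20-letter amino-acid alphabet: three hydrophobicity scales
(a Tanford-type transfer free energy scale, Kyte–Doolittle, and the
Eisenberg consensus), polarizability (Charton & Charton), polarity
(Grantham), and factor-analytic secondary-structure and codon-diversity
scores. The first five drive the k-interval product factors; all seven
supply the basic first-order features.

The numeric values are packaged constants taken from the standard
literature tabulations. They can be replaced wholesale with
:func:`load_scales_tsv` for users who prefer their own parameterisation;
everything downstream only assumes "one real number per residue type".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "ALPHABET",
    "ScaleTable",
    "default_scales",
    "load_scales_tsv",
    "PKA_TABLE",
    "VDW_RADII",
    "THREE_TO_ONE",
]

#: The 20 canonical residues, one-letter codes, in alphabetical order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ScaleTable:
    """One named physicochemical property scale over the 20-residue alphabet."""

    property_name: str
    values: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(ALPHABET) - set(self.values)
        extra = set(self.values) - set(ALPHABET)
        if missing or extra:
            raise ValueError(
                f"scale {self.property_name!r} must cover exactly the 20-residue "
                f"alphabet (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def __call__(self, residue: str) -> float:
        return self.values[residue]


# Tanford-type hydrophobicity: side-chain transfer free energies (kcal/mol),
# Jones's tabulation of the Nozaki–Tanford measurements.
_HYDROPHOBICITY_TANFORD = {
    "A": 0.87, "C": 1.52, "D": 0.66, "E": 0.67, "F": 2.87,
    "G": 0.10, "H": 0.87, "I": 3.15, "K": 1.64, "L": 2.17,
    "M": 1.67, "N": 0.09, "P": 2.77, "Q": 0.00, "R": 0.85,
    "S": 0.07, "T": 0.07, "V": 1.87, "W": 3.77, "Y": 2.67,
}

# Polarizability parameter (Charton & Charton 1982).
_POLARIZABILITY = {
    "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290,
    "G": 0.000, "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186,
    "M": 0.221, "N": 0.134, "P": 0.131, "Q": 0.180, "R": 0.291,
    "S": 0.062, "T": 0.108, "V": 0.140, "W": 0.409, "Y": 0.298,
}

# Polarity (Grantham 1974).
_POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}

# Factor-analytic propensity for secondary structure (helix/turn factor
# score; positive values favour coil/turn, negative favour helix/strand).
_SECONDARY_STRUCTURE = {
    "A": -1.302, "C": 0.465, "D": 0.302, "E": -1.453, "F": -0.590,
    "G": 1.652, "H": -0.417, "I": -0.547, "K": -0.561, "L": -0.987,
    "M": -1.524, "N": 0.828, "P": 2.081, "Q": -0.179, "R": -0.055,
    "S": 1.399, "T": 0.326, "V": -0.279, "W": 0.009, "Y": 0.830,
}

# Factor-analytic codon diversity / composition score.
_CODON_DIVERSITY = {
    "A": 1.570, "C": -1.020, "D": -0.259, "E": 0.113, "F": -0.397,
    "G": 1.045, "H": -1.474, "I": 0.393, "K": -0.277, "L": 1.266,
    "M": -1.005, "N": -0.169, "P": 0.421, "Q": -0.503, "R": 0.440,
    "S": 0.670, "T": 0.908, "V": 1.242, "W": -2.128, "Y": -0.838,
}

# Kyte–Doolittle hydropathy index (1982).
_HYDROPHOBICITY_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Eisenberg normalized consensus hydrophobicity (1984).
_HYDROPHOBICITY_EISENBERG = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

#: Canonical ordering of the seven scales. The first five feed the
#: k-interval product factors; all seven feed the basic first-order block.
_SCALE_ORDER = (
    ("hydrophobicity_tanford", _HYDROPHOBICITY_TANFORD),
    ("polarizability", _POLARIZABILITY),
    ("polarity", _POLARITY),
    ("secondary_structure", _SECONDARY_STRUCTURE),
    ("codon_diversity", _CODON_DIVERSITY),
    ("hydrophobicity_kyte_doolittle", _HYDROPHOBICITY_KD),
    ("hydrophobicity_eisenberg", _HYDROPHOBICITY_EISENBERG),
)


def default_scales() -> list[ScaleTable]:
    """Return the seven packaged scales in canonical order."""
    return [ScaleTable(name, dict(vals)) for name, vals in _SCALE_ORDER]


def load_scales_tsv(path: str | Path) -> list[ScaleTable]:
    """Read scales from a TSV file: header ``residue<TAB>name1<TAB>name2...``,
    one row per residue, exactly 20 rows covering the alphabet.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty scale file")
    header = lines[0].split("\t")
    if header[0].lower() not in ("residue", "aa"):
        raise ValueError(f"{path}: first column must be 'residue', got {header[0]!r}")
    names = header[1:]
    tables: dict[str, dict[str, float]] = {n: {} for n in names}
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
        res = parts[0].strip().upper()
        for name, raw in zip(names, parts[1:]):
            tables[name][res] = float(raw)
    return [ScaleTable(n, tables[n]) for n in names]


# Intrinsic ionisation constants per residue type (pH units): pK1 for the
# alpha-carboxyl group, pK2 for the alpha-amino group. These are the
# textbook free-amino-acid values; structure-aware estimates from a pKa
# predictor can be injected via structure.electric_features(import_table=...).
PKA_TABLE: dict[str, tuple[float, float]] = {
    "A": (2.34, 9.69), "R": (2.17, 9.04), "N": (2.02, 8.80),
    "D": (1.88, 9.60), "C": (1.96, 10.28), "E": (2.19, 9.67),
    "Q": (2.17, 9.13), "G": (2.34, 9.60), "H": (1.82, 9.17),
    "I": (2.36, 9.68), "L": (2.36, 9.60), "K": (2.18, 8.95),
    "M": (2.28, 9.21), "F": (1.83, 9.13), "P": (1.99, 10.96),
    "S": (2.21, 9.15), "T": (2.11, 9.62), "W": (2.38, 9.39),
    "Y": (2.20, 9.11), "V": (2.32, 9.62),
}

# Single van der Waals radius per element (Å), Bondi-style; heavy atoms only.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
}
VDW_DEFAULT = 1.70

# Three-letter → one-letter residue codes; MSE (selenomethionine) maps to M.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
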