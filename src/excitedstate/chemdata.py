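"""Chemical reference data: atomic form factors, masses, van der Waals radii,
and amino-acid heavy-atom topology.

Form factors are 4-Gaussian Cromer-Mann parameterizations (International
Tables for Crystallography, Vol. C).  ``form_factor`` optionally folds
implicit hydrogens into the heavy atom as a constant increment of one
electron per hydrogen (united-atom treatment).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CROMER_MANN",
    "ATOMIC_MASSES",
    "VDW_RADII",
    "AMINO_ACIDS",
    "SIDECHAIN_ATOMS",
    "BACKBONE_ATOMS",
    "HYDROGEN_COUNTS",
    "form_factor",
    "hydrogen_count",
    "element_from_atom_name",
]

# element -> (a[4], b[4], c)
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
}

# Bondi radii (Å)
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}

BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

# Heavy side-chain atoms per residue type (PDB v3 naming).
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

AMINO_ACIDS: frozenset[str] = frozenset(SIDECHAIN_ATOMS)

# Implicit hydrogens attached to each heavy atom (neutral backbone amide,
# charged Lys/Arg, deprotonated Asp/Glu, neutral His with H on ND1).
_BACKBONE_H = {"N": 1, "CA": 1, "C": 0, "O": 0, "OXT": 0}

_SIDECHAIN_H: dict[str, dict[str, int]] = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
    "ASP": {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
    "CYS": {"CB": 2, "SG": 1},
    "GLN": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
    "GLY": {},
    "HIS": {"CB": 2, "CG": 0, "ND1": 1, "CD2": 1, "CE1": 1, "NE2": 0},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
    "PHE": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 0},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 0, "NE1": 1, "CE2": 0,
            "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1},
    "TYR": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1,
            "CZ": 0, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
}

HYDROGEN_COUNTS: dict[str, dict[str, int]] = {
    res: {**_BACKBONE_H, **sc} for res, sc in _SIDECHAIN_H.items()
}
HYDROGEN_COUNTS["GLY"]["CA"] = 2
HYDROGEN_COUNTS["PRO"]["N"] = 0


class UnknownElementError(KeyError):
    """Raised when an element has no tabulated form factor."""


def form_factor(element: str, q: np.ndarray, n_hydrogens: int = 0) -> np.ndarray:
    """Cromer-Mann X-ray form factor f(q), in electrons.

    Parameters
    ----------
    element : element symbol (upper case)
    q : momentum transfer grid, Å⁻¹ (q = 4π sin(θ)/λ)
    n_hydrogens : implicit hydrogens folded in as a constant +1 e⁻ each
    """
    try:
        a, b, c = CROMER_MANN[element.upper()]
    except KeyError:
        raise UnknownElementError(
            f"no form factor tabulated for element {element!r}"
        ) from None
    q = np.asarray(q, dtype=float)
    s2 = (q / (4.0 * np.pi)) ** 2
    f = np.full_like(q, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f + float(n_hydrogens)


def hydrogen_count(residue_name: str, atom_name: str) -> int:
    """Implicit hydrogens attached to a heavy atom; 0 if unknown."""
    return HYDROGEN_COUNTS.get(residue_name.upper(), {}).get(atom_name.upper(), 0)


def element_from_atom_name(atom_name: str) -> str:
    """Best-effort element guess from a PDB atom name (protein atoms)."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    # two-character elements used in proteins
    head = name.lstrip("0123456789")
    if head[:2].upper() in ("SE", "FE", "ZN", "MG", "MN"):
        return head[:2].upper()
    return head[0].upper()
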