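"""Structure representation, PDB I/O, geometry, and in-silico mutation.

Structures are flat arrays of atoms (element, name, residue index/name,
chain, coordinates).  Residue indices are 1-based throughout the package.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .chemdata import (
    AMINO_ACIDS,
    ATOMIC_MASSES,
    BACKBONE_ATOMS,
    SIDECHAIN_ATOMS,
    element_from_atom_name,
)

__all__ = [
    "Structure",
    "ContactMap",
    "PDBParseError",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "mutate_residue",
    "radius_of_gyration",
    "rmsd_superposed",
    "superpose",
    "contact_map",
]


class PDBParseError(ValueError):
    """Malformed or empty PDB input."""


@dataclasses.dataclass
class Structure:
    """A set of atoms with residue/chain bookkeeping.

    All per-atom sequences share one length; coordinates are (n_atoms, 3)
    in Å.  Residue indices are the author-assigned PDB numbers (1-based).
    """

    elements: list[str]
    atom_names: list[str]
    res_indices: np.ndarray
    res_names: list[str]
    chain_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.res_indices = np.asarray(self.res_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if not (len(self.atom_names) == len(self.res_names)
                == len(self.chain_ids) == self.res_indices.shape[0]
                == self.coords.shape[0] == n):
            raise ValueError("inconsistent per-atom array lengths")
        if n and self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        # residue indices must be non-decreasing within each chain
        for chain in set(self.chain_ids):
            idx = self.res_indices[[c == chain for c in self.chain_ids]]
            if np.any(np.diff(idx) < 0):
                raise ValueError(
                    f"residue indices decrease within chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def residue_ids(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue index) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for c, i in zip(self.chain_ids, self.res_indices):
            seen.setdefault((c, int(i)), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def residue_name(self, residue_index: int, chain: str | None = None) -> str:
        for name, idx, cid in zip(self.res_names, self.res_indices, self.chain_ids):
            if idx == residue_index and (chain is None or cid == chain):
                return name
        raise KeyError(f"residue {residue_index} not found")

    def atom_index(self, residue_index: int, atom_name: str,
                   chain: str | None = None) -> int:
        for k, (nm, idx, cid) in enumerate(
                zip(self.atom_names, self.res_indices, self.chain_ids)):
            if idx == residue_index and nm == atom_name and (
                    chain is None or cid == chain):
                return k
        raise KeyError(f"atom {atom_name!r} of residue {residue_index} not found")

    def select(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        pick = np.flatnonzero(mask)
        return Structure(
            elements=[self.elements[i] for i in pick],
            atom_names=[self.atom_names[i] for i in pick],
            res_indices=self.res_indices[pick],
            res_names=[self.res_names[i] for i in pick],
            chain_ids=[self.chain_ids[i] for i in pick],
            coords=self.coords[pick],
        )

    def select_atom_names(self, names: Iterable[str]) -> "Structure":
        names = set(names)
        return self.select(np.array([a in names for a in self.atom_names]))

    def translated(self, shift) -> "Structure":
        s = dataclasses.replace(self, coords=self.coords + np.asarray(shift, float))
        return s

    def transformed(self, rotation: np.ndarray, translation=0.0) -> "Structure":
        coords = self.coords @ np.asarray(rotation, float).T + translation
        return dataclasses.replace(self, coords=coords)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 12.011) for e in self.elements])


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/HETATM records; strict enough to flag bad lines)
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip()
        chain = line[21]
        res_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = element_from_atom_name(name)
    return name, altloc, res_name, chain, res_index, (x, y, z), element.upper()


def read_pdb_models(path, include_hetatm: bool = False,
                    include_hydrogens: bool = False) -> list[Structure]:
    """Parse every MODEL of a PDB file into a list of Structures.

    Waters are always excluded; other HETATM records only on request.
    Alternate locations other than ' '/'A' are dropped.
    """
    path = Path(path)
    models: list[Structure] = []
    cur: list[tuple] = []

    def flush():
        nonlocal cur
        if cur:
            models.append(_atoms_to_structure(cur))
            cur = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                flush()
            elif rec in ("ATOM", "HETATM"):
                name, altloc, res_name, chain, res_index, xyz, element = \
                    _parse_atom_line(line, lineno)
                if altloc not in (" ", "A"):
                    continue
                if res_name in _WATER_NAMES:
                    continue
                if rec == "HETATM" and not include_hetatm:
                    continue
                if element == "H" and not include_hydrogens:
                    continue
                cur.append((element, name, res_index, res_name, chain, xyz))
    flush()
    if not models:
        raise PDBParseError(f"no ATOM records found in {path}")
    return models


def _atoms_to_structure(atoms: list[tuple]) -> Structure:
    return Structure(
        elements=[a[0] for a in atoms],
        atom_names=[a[1] for a in atoms],
        res_indices=np.array([a[2] for a in atoms]),
        res_names=[a[3] for a in atoms],
        chain_ids=[a[4] for a in atoms],
        coords=np.array([a[5] for a in atoms], dtype=float),
    )


def read_pdb(path, include_hetatm: bool = False) -> Structure:
    """Read the first model of a PDB file (waters excluded)."""
    return read_pdb_models(path, include_hetatm=include_hetatm)[0]


def write_pdb(s: Structure, path) -> None:
    """Write a Structure as minimal ATOM records."""
    with open(path, "w") as fh:
        for k in range(s.n_atoms):
            name = s.atom_names[k]
            # PDB alignment rule: 1-char element names start in column 14
            pname = f" {name:<3s}" if len(name) < 4 and len(s.elements[k]) == 1 else f"{name:<4s}"
            x, y, z = s.coords[k]
            fh.write(
                f"ATOM  {k + 1:5d} {pname}{'':1s}{s.res_names[k]:>3s} "
                f"{s.chain_ids[k]:1s}{int(s.res_indices[k]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {s.elements[k]:>2s}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def mutate_residue(s: Structure, residue_index: int, new_residue_name: str,
                   chain: str | None = None) -> Structure:
    """Rename a residue and truncate side-chain atoms absent from the target.

    Backbone atoms and Cβ are always retained; no atoms are built.  This is
    sufficient for low-resolution observables (SAXS, 4.5 Å contacts, Rg).
    """
    new_residue_name = new_residue_name.upper()
    if new_residue_name not in AMINO_ACIDS:
        raise ValueError(f"unknown residue name {new_residue_name!r}")
    target_atoms = BACKBONE_ATOMS | {"CB"} | set(SIDECHAIN_ATOMS[new_residue_name])
    hit = np.array([
        (idx == residue_index and (chain is None or cid == chain))
        for idx, cid in zip(s.res_indices, s.chain_ids)
    ])
    if not hit.any():
        raise KeyError(f"residue {residue_index} not found")
    keep = ~hit | np.array([a in target_atoms for a in s.atom_names])
    out = s.select(keep)
    res_names = [
        new_residue_name if (idx == residue_index and (chain is None or cid == chain))
        else nm
        for nm, idx, cid in zip(out.res_names, out.res_indices, out.chain_ids)
    ]
    return dataclasses.replace(out, res_names=res_names)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def radius_of_gyration(s: Structure, mass_weighted: bool = False) -> float:
    """Root-mean-square atom distance from the (mass-weighted) centroid, Å."""
    if s.n_atoms < 2:
        raise ValueError("radius of gyration requires at least 2 atoms")
    w = s.masses() if mass_weighted else np.ones(s.n_atoms)
    com = np.average(s.coords, axis=0, weights=w)
    d2 = np.sum((s.coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=w)))


def _resolve_selection(s: Structure, atom_selection) -> np.ndarray:
    if atom_selection is None:
        return s.coords
    if isinstance(atom_selection, str):
        atom_selection = [atom_selection]
    if all(isinstance(a, str) for a in atom_selection):
        names = set(atom_selection)
        mask = np.array([a in names for a in s.atom_names])
        return s.coords[mask]
    return s.coords[np.asarray(atom_selection)]


def superpose(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of coordinate set b onto a.

    Returns (rotation, translation, rmsd) such that b @ R.T + t ≈ a.
    Reflections are excluded via the determinant sign correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    b_fit = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((b_fit - a0) ** 2, axis=1))))
    return rot, ca - cb @ rot.T, rmsd


def rmsd_superposed(a: Structure, b: Structure, atom_selection=None) -> float:
    """Minimal RMSD (Å) between two structures over rigid transforms."""
    xa = _resolve_selection(a, atom_selection)
    xb = _resolve_selection(b, atom_selection)
    if xa.shape != xb.shape:
        raise ValueError(
            f"selected atom counts differ: {xa.shape[0]} vs {xb.shape[0]}")
    return superpose(xa, xb)[2]


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ContactMap:
    """Symmetric residue-residue contact indicator or density matrix.

    Per-structure maps hold {0,1}; ensemble densities lie in [0,1].  The
    diagonal and the |i-j| < 3 band are identically zero.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("contact matrix must be symmetric")
        if m.size and (m.min() < -1e-12 or m.max() > 1 + 1e-12):
            raise ValueError("contact values must lie in [0, 1]")
        n = m.shape[0]
        i, j = np.indices((n, n))
        m = np.where(np.abs(i - j) < 3, 0.0, m)
        self.matrix = m

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# contact map  n_residues={self.n_residues}\n")
            np.savetxt(fh, self.matrix, fmt="%.6g")

    @classmethod
    def read(cls, path) -> "ContactMap":
        return cls(np.loadtxt(path))


def contact_map(s: Structure, cutoff: float = 4.5, min_seq_sep: int = 3) -> ContactMap:
    """Binary residue contact map: min heavy-atom distance < cutoff.

    Residues are taken in order of appearance; separation is measured on
    that 1..n ordering.  Pairs with |i-j| < max(min_seq_sep, 3) are zero.
    """
    if s.n_atoms == 0:
        raise ValueError("empty structure")
    rids = s.residue_ids
    pos = {rid: k for k, rid in enumerate(rids)}
    atom_res = np.array([pos[(c, int(i))] for c, i in
                         zip(s.chain_ids, s.res_indices)])
    n = len(rids)
    d = cdist(s.coords, s.coords)
    mind = np.full((n, n), np.inf)
    # reduce atom-pair distances to residue-pair minima
    for r in range(n):
        sel = atom_res == r
        if sel.any():
            block = d[sel]
            np.minimum.at(mind[r], atom_res, block.min(axis=0))
    mat = (mind < cutoff).astype(float)
    i, j = np.indices((n, n))
    mat[np.abs(i - j) < max(min_seq_sep, 3)] = 0.0
    mat = np.maximum(mat, mat.T)
    return ContactMap(mat)
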