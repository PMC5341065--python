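"""Weighted ensemble contact densities, difference maps, and feature-based
state classification."""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from .core_structures import ContactMap

__all__ = [
    "FeatureDefinition",
    "weighted_contact_density",
    "difference_map",
    "classify_states",
    "helix_fraction",
]


@dataclasses.dataclass
class FeatureDefinition:
    """A named set of residue pairs with a containment threshold.

    A state "contains" the feature when at least ``threshold`` of the
    defining pairs are in contact.  The threshold is mandatory so the
    operational definition is always explicit.
    """

    name: str
    pairs: list[tuple[int, int]]      # 1-based residue indices
    threshold: float

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("feature needs at least one residue pair")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        self.pairs = [(int(i), int(j)) for i, j in self.pairs]

    @classmethod
    def from_json(cls, path) -> "FeatureDefinition":
        with open(path) as fh:
            d = json.load(fh)
        return cls(name=d["name"], pairs=[tuple(p) for p in d["pairs"]],
                   threshold=d["threshold"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "pairs": self.pairs,
                       "threshold": self.threshold}, fh, indent=1)


def weighted_contact_density(maps: Sequence[ContactMap],
                             weights: np.ndarray) -> ContactMap:
    """Population-weighted contact density: density(i,j) = Σ_k w_k c_k(i,j)."""
    weights = np.asarray(weights, dtype=float)
    if len(maps) != weights.size:
        raise ValueError("map count does not match weight count")
    n = maps[0].n_residues
    if any(m.n_residues != n for m in maps):
        raise ValueError("contact maps differ in residue count")
    dens = np.zeros((n, n))
    for w, m in zip(weights, maps):
        dens += w * m.matrix
    return ContactMap(np.clip(dens, 0.0, 1.0))


def difference_map(a: ContactMap, b: ContactMap) -> np.ndarray:
    """Signed elementwise density difference a − b, in [−1, 1]."""
    if a.n_residues != b.n_residues:
        raise ValueError("contact maps differ in residue count")
    return a.matrix - b.matrix


def _contains(m: ContactMap, feature: FeatureDefinition) -> bool:
    n = m.n_residues
    formed = 0
    for i, j in feature.pairs:
        if not (1 <= i <= n and 1 <= j <= n):
            raise ValueError(f"feature pair ({i}, {j}) out of range 1..{n}")
        formed += m.matrix[i - 1, j - 1] > 0.5
    return formed >= feature.threshold * len(feature.pairs) - 1e-12


def classify_states(maps: Sequence[ContactMap], feature: FeatureDefinition,
                    weights: np.ndarray | None = None):
    """Flag feature-containing states; optionally their ensemble fraction.

    Returns (mask, fraction); fraction is None when no weights are given.
    """
    mask = np.array([_contains(m, feature) for m in maps])
    fraction = None
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.size != len(maps):
            raise ValueError("weight count mismatch")
        fraction = float(weights[mask].sum())
    return mask, fraction


def helix_fraction(m: ContactMap) -> float:
    """Crude helicity proxy: fraction of residues i with an (i, i+4) contact.

    This is a contact-pattern stand-in for DSSP-style assignment and is only
    meaningful for maps built with min_seq_sep <= 4.
    """
    n = m.n_residues
    if n < 5:
        return 0.0
    hits = sum(m.matrix[i, i + 4] > 0.5 for i in range(n - 4))
    return hits / (n - 4)
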