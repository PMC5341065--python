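"""Deterministic toy-data generators with known ground truth.

Toy ensembles are coarse bead chains (one carbon-like pseudo-atom per
residue) spanning compact, extended, and feature-bearing archetypes, with
per-state SAXS profiles, noisy synthetic "experiments", and two-regime
kinetic models whose stationary distributions and RMSD pairing answers are
known by construction.  Everything is a pure function of spec + seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core_structures import ContactMap, Structure, contact_map
from .msm_kinetics import IsomerCoupling, TransitionMatrix
from .saxs_forward import SAXSProfile, debye_profile

__all__ = [
    "ToyEnsembleSpec",
    "SyntheticExperiment",
    "ToyEnsemble",
    "generate_toy_ensemble",
    "generate_synthetic_experiment",
    "generate_two_regime_msm",
    "standard_fixture",
    "DEFAULT_Q_GRID",
]

# Wide enough in q that 20 coarse-grained states are spectrally
# distinguishable (information content scales with q_max * D_max).
DEFAULT_Q_GRID = np.linspace(0.01, 0.80, 120)

_BOND = 3.8          # Cα-Cα virtual bond, Å
_CLASH = 3.0         # bead self-avoidance, Å
_FEATURE_DIST = 4.0  # realized feature-pair distance, Å (< 4.5 contact cutoff)


@dataclasses.dataclass
class ToyEnsembleSpec:
    """Recipe for a toy conformational ensemble with known weights.

    ``archetypes`` holds one entry per state: "compact", "extended", or a
    ("feature", pairs) tuple with 1-based residue pairs to realize as
    non-native contacts.
    """

    n_residues: int
    archetypes: list
    weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size != len(self.archetypes):
                raise ValueError("weights length must equal state count")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            self.weights = self.weights / self.weights.sum()

    @property
    def n_states(self) -> int:
        return len(self.archetypes)


@dataclasses.dataclass
class ToyEnsemble:
    structures: list[Structure]
    contact_maps: list[ContactMap]
    profiles: list[SAXSProfile]
    weights: np.ndarray
    spec: ToyEnsembleSpec


def _bead_structure(coords: np.ndarray) -> Structure:
    n = coords.shape[0]
    return Structure(
        elements=["C"] * n,
        atom_names=["CA"] * n,
        res_indices=np.arange(1, n + 1),
        res_names=["UNK"] * n,      # no implicit hydrogens folded in
        chain_ids=["A"] * n,
        coords=coords,
    )


def _compact_chain(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Self-avoiding random walk confined to a sphere."""
    for _attempt in range(200):
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _try in range(300):
                step = rng.normal(size=3)
                step *= _BOND / np.linalg.norm(step)
                cand = coords[i - 1] + step
                if np.linalg.norm(cand) > radius:
                    continue
                if i > 1 and np.min(
                        np.linalg.norm(coords[:i - 1] - cand, axis=1)) < _CLASH:
                    continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return coords - coords.mean(axis=0)
    raise RuntimeError("failed to grow a compact chain (radius too small?)")


def _extended_chain(rng: np.random.Generator, n: int, jitter: float) -> np.ndarray:
    coords = np.zeros((n, 3))
    for i in range(1, n):
        d = np.array([1.0, jitter * rng.normal(), jitter * rng.normal()])
        coords[i] = coords[i - 1] + _BOND * d / np.linalg.norm(d)
    return coords - coords.mean(axis=0)


def _relax_feature(coords: np.ndarray, pairs: list[tuple[int, int]],
                   n_iter: int = 1500, lr: float = 0.02) -> np.ndarray:
    """Gradient descent pulling feature pairs to contact distance while
    preserving bond lengths and self-avoidance."""
    x = coords.copy()
    n = x.shape[0]
    p = np.array([(i - 1, j - 1) for i, j in pairs])
    for _ in range(n_iter):
        grad = np.zeros_like(x)
        # bonds
        d = x[1:] - x[:-1]
        dist = np.linalg.norm(d, axis=1, keepdims=True)
        g = 2.0 * (dist - _BOND) * d / np.maximum(dist, 1e-9)
        grad[1:] += g
        grad[:-1] -= g
        # feature pairs
        d = x[p[:, 1]] - x[p[:, 0]]
        dist = np.linalg.norm(d, axis=1, keepdims=True)
        g = 2.0 * (dist - _FEATURE_DIST) * d / np.maximum(dist, 1e-9)
        grad[p[:, 1]] += g
        grad[p[:, 0]] -= g
        # soft repulsion for non-bonded, non-feature pairs
        diff = x[:, None, :] - x[None, :, :]
        dd = np.linalg.norm(diff, axis=-1)
        i, j = np.triu_indices(n, k=2)
        close = dd[i, j] < _CLASH
        fp = {tuple(sorted(t)) for t in map(tuple, p)}
        for a, b in zip(i[close], j[close]):
            if (a, b) in fp:
                continue
            v = x[b] - x[a]
            r = np.linalg.norm(v)
            g = -2.0 * (_CLASH - r) * v / max(r, 1e-9)
            grad[b] += g
            grad[a] -= g
        x -= lr * grad
    return x - x.mean(axis=0)


def generate_toy_ensemble(spec: ToyEnsembleSpec,
                          q_grid: np.ndarray | None = None) -> ToyEnsemble:
    """Build structures, contact maps, and SAXS profiles for a toy spec.

    Feature-bearing states are verified to realize their contact pairs
    under the package contact definition; failure raises.
    """
    rng = np.random.default_rng(spec.seed)
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, float)
    n = spec.n_residues
    base_radius = 2.4 * n ** (1.0 / 3.0)
    structures: list[Structure] = []
    for arch in spec.archetypes:
        if arch == "compact" or (isinstance(arch, (tuple, list))
                                 and arch[0] == "compact"):
            scale = arch[1] if isinstance(arch, (tuple, list)) else \
                0.85 + 0.6 * rng.random()
            coords = _compact_chain(rng, n, base_radius * scale)
        elif arch == "extended" or (isinstance(arch, (tuple, list))
                                    and arch[0] == "extended"):
            jitter = arch[1] if isinstance(arch, (tuple, list)) else \
                0.1 + 0.6 * rng.random()
            coords = _extended_chain(rng, n, jitter=jitter)
        elif isinstance(arch, (tuple, list)) and arch[0] == "feature":
            pairs = [(int(i), int(j)) for i, j in arch[1]]
            for i, j in pairs:
                if abs(i - j) < 3:
                    raise ValueError(
                        f"feature pair ({i}, {j}) unrealizable: |i-j| < 3 is "
                        "masked by the contact definition")
                if not (1 <= i <= n and 1 <= j <= n):
                    raise ValueError(f"feature pair ({i}, {j}) out of range")
            coords = _compact_chain(rng, n, base_radius * 1.2)
            coords = _relax_feature(coords, pairs)
        else:
            raise ValueError(f"unknown archetype {arch!r}")
        structures.append(_bead_structure(coords))

    maps = [contact_map(s) for s in structures]
    for k, arch in enumerate(spec.archetypes):
        if isinstance(arch, (tuple, list)) and arch[0] == "feature":
            for i, j in arch[1]:
                if maps[k].matrix[i - 1, j - 1] < 0.5:
                    raise ValueError(
                        f"state {k}: feature pair ({i}, {j}) not realized")
    profiles = [debye_profile(s, q, fold_hydrogens=False) for s in structures]
    if spec.weights is None:
        weights = rng.dirichlet(np.ones(spec.n_states))
    else:
        weights = spec.weights.copy()
    return ToyEnsemble(structures=structures, contact_maps=maps,
                       profiles=profiles, weights=weights, spec=spec)


@dataclasses.dataclass
class SyntheticExperiment:
    true_weights: np.ndarray
    clean: SAXSProfile
    noise: float
    observed: SAXSProfile
    seed: int


def generate_synthetic_experiment(profiles: Sequence[SAXSProfile],
                                  true_weights: np.ndarray, noise: float,
                                  seed: int = 0,
                                  sigma_floor: float = 0.01) -> SyntheticExperiment:
    """Noisy ensemble-average profile with recorded ground truth.

    Gaussian noise of relative magnitude ``noise`` is added per point; the
    reported σ never falls below ``sigma_floor`` (relative) so χ² stays
    defined for noiseless experiments.
    """
    w = np.asarray(true_weights, dtype=float)
    w = w / w.sum()
    q = profiles[0].q
    clean_i = w @ np.array([p.intensity for p in profiles])
    sigma = max(noise, sigma_floor) * clean_i
    rng = np.random.default_rng(seed)
    observed_i = clean_i + noise * clean_i * rng.standard_normal(q.size)
    return SyntheticExperiment(
        true_weights=w, clean=SAXSProfile(q, clean_i), noise=noise,
        observed=SAXSProfile(q, observed_i, sigma), seed=seed)


def generate_two_regime_msm(n: int, m: int, k: float, lag: float,
                            seed: int = 0, mixing: float = 0.5) -> dict:
    """Two ergodic blocks plus geometry with a known RMSD pairing answer.

    Each block is a lazy Metropolis chain on a path graph with a random
    Dirichlet stationary distribution (held exactly).  Reference structures
    are scaled copies of one rigid 4-bead shape: cis state i has scale
    1 + 0.2 i, trans state j scale 1 + 0.2 j + 0.08, so trans j pairs with
    cis j and the neighbor-RMSD filter retains pairs exactly for
    j < min(n, m).
    """
    if n < 2 or m < 2:
        raise ValueError("each regime needs at least 2 states")
    rng = np.random.default_rng(seed)

    def block(nstates: int, pi: np.ndarray) -> TransitionMatrix:
        t = np.zeros((nstates, nstates))
        for i in range(nstates):
            for j in (i - 1, i + 1):
                if 0 <= j < nstates:
                    t[i, j] = 0.5 * min(1.0, pi[j] / pi[i])
            t[i, i] = 1.0 - t[i].sum()
        lazy = (1.0 - mixing) * np.eye(nstates) + mixing * t
        return TransitionMatrix(lazy, lag=lag)

    pi_cis = rng.dirichlet(np.ones(n) * 5.0)
    pi_trans = rng.dirichlet(np.ones(m) * 5.0)
    t_cis = block(n, pi_cis)
    t_trans = block(m, pi_trans)

    base = np.array([[0.0, 0.0, 0.0], [_BOND, 0.0, 0.0],
                     [_BOND, _BOND, 0.0], [0.0, _BOND, _BOND]])
    structures_cis = [_bead_structure(base * (1.0 + 0.2 * i)) for i in range(n)]
    structures_trans = [_bead_structure(base * (1.0 + 0.2 * j + 0.08))
                        for j in range(m)]
    expected_pairs = [(j, j) for j in range(min(n, m))]
    return {
        "T_cis": t_cis,
        "T_trans": t_trans,
        "coupling": IsomerCoupling(k=k, pairs=None),
        "structures_cis": structures_cis,
        "structures_trans": structures_trans,
        "expected_pairs": expected_pairs,
        "pi_cis": pi_cis,
        "pi_trans": pi_trans,
    }


def standard_fixture(seed: int = 1234, noise: float = 0.03,
                     q_grid: np.ndarray | None = None) -> dict:
    """The standard test ensemble: 30 residues, 20 states, 3 archetypes.

    Returns the toy ensemble, its noisy synthetic experiment, and a
    noiseless one (σ floored at 1% for χ² weighting).
    """
    feature_pairs = [(5, 15), (6, 14), (7, 13)]
    # deterministic parameter spreads and distinct feature pair sets keep the
    # 20 states spectrally distinguishable
    archetypes = (
        [("compact", s) for s in np.linspace(0.9, 1.6, 7)] +
        [("extended", j) for j in np.linspace(0.12, 0.70, 6)] +
        [("feature", feature_pairs),
         ("feature", [(3, 20), (4, 19), (5, 18)]),
         ("feature", [(10, 28), (11, 27), (12, 26)]),
         ("feature", [(2, 29), (3, 28)]),
         ("feature", [(8, 22), (9, 21), (10, 20)]),
         ("feature", [(6, 25), (7, 24)]),
         ("feature", [(15, 30), (16, 29)])]
    )
    spec = ToyEnsembleSpec(n_residues=30, archetypes=archetypes, seed=seed)
    ens = generate_toy_ensemble(spec, q_grid=q_grid)
    # Ground-truth weights: uniform prior plus a perturbation inside the
    # identifiable subspace of the profile map (top singular directions of
    # the sigma-weighted, mean/offset-projected state-profile matrix).
    # Smooth scattering kernels have exponentially decaying spectra, so a
    # fully random 20-dim weight vector is NOT recoverable from one profile;
    # restricting the truth to the well-conditioned subspace is what makes
    # this a fair recovery benchmark.
    nst = spec.n_states
    rng = np.random.default_rng(seed + 17)
    A = np.array([p.intensity for p in ens.profiles])
    uniform = np.full(nst, 1.0 / nst)
    tangent = np.eye(nst) - 1.0 / nst             # simplex tangent projector
    nq = A.shape[1]
    coef = rng.standard_normal(6)
    weights = uniform
    # χ² is evaluated after an affine (scale + offset) fit against the
    # noisy target with σ proportional to the clean target, so both the
    # metric and the invisible affine directions depend on the truth being
    # constructed; iterate to self-consistency
    for _ in range(5):
        clean = weights @ A
        sigma_rel = 0.01 * clean
        aw = A / sigma_rel
        affine = np.column_stack([np.ones(nq), clean / sigma_rel])
        qmat, _ = np.linalg.qr(affine)
        aw = aw - (aw @ qmat) @ qmat.T
        u, svals, _ = np.linalg.svd(tangent @ aw, full_matrices=False)
        n_dir = int(np.sum(svals > 0.08 * svals[0]))
        n_dir = max(2, min(6, n_dir))
        basis = u[:, :n_dir]                      # weight-space directions
        direction = basis @ coef[:n_dir]
        direction -= direction.mean()
        scale = 0.9 * (uniform.min() - 0.005) / np.abs(direction).max()
        weights = np.clip(uniform + scale * direction, 1e-9, None)
        weights = weights / weights.sum()
    ens.weights = weights
    noisy = generate_synthetic_experiment(ens.profiles, ens.weights,
                                          noise=noise, seed=seed + 1)
    noiseless = generate_synthetic_experiment(ens.profiles, ens.weights,
                                              noise=0.0, seed=seed + 2)
    return {"ensemble": ens, "experiment": noisy, "noiseless": noiseless,
            "feature_pairs": feature_pairs}
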