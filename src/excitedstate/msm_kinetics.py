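"""Markov-state-model estimation and kinetics.

Covers tICA featurization, k-centers clustering, transition-matrix
estimation from discrete trajectories, population propagation, and the
combination of two slowly interconverting isomeric regimes into a single
near-block-diagonal model coupled through an experimental rate constant.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core_structures import Structure, rmsd_superposed

__all__ = [
    "TransitionMatrix",
    "IsomerCoupling",
    "read_dtraj",
    "write_dtraj",
    "rate_to_probability",
    "estimate_transition_matrix",
    "propagate",
    "stationary_distribution",
    "tica_decompose",
    "kcenters_cluster",
    "derive_isomer_pairs",
    "combine_isomer_models",
]

_ROW_TOL = 1e-10


@dataclasses.dataclass
class TransitionMatrix:
    """Row-stochastic transition probability matrix at a fixed lag time."""

    matrix: np.ndarray
    lag: float
    labels: list | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.matrix, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if self.lag <= 0:
            raise ValueError("lag time must be positive")
        if np.any(t < -1e-15) or np.any(t > 1 + 1e-12):
            raise ValueError("transition probabilities outside [0, 1]")
        rows = t.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_TOL):
            raise ValueError("rows must sum to 1 within 1e-10")
        self.matrix = t
        if self.labels is None:
            self.labels = list(range(t.shape[0]))
        elif len(self.labels) != t.shape[0]:
            raise ValueError("label count mismatch")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# transition matrix  n={self.n_states}  lag={self.lag!r}\n")
            np.savetxt(fh, self.matrix, fmt="%.12g")

    @classmethod
    def read(cls, path) -> "TransitionMatrix":
        with open(path) as fh:
            header = fh.readline()
        lag = None
        for tok in header.replace("#", "").split():
            if tok.startswith("lag="):
                lag = float(tok[4:])
        if lag is None:
            raise ValueError(f"missing lag= in header of {path}")
        return cls(np.loadtxt(path, comments="#"), lag=lag)


@dataclasses.dataclass
class IsomerCoupling:
    """Experimental isomerization rate and allowed trans-cis state pairs.

    ``pairs`` is a list of (trans_state, cis_state) index tuples, or None
    to derive pairs from representative structures via the RMSD rule.
    """

    k: float
    pairs: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate constant must be non-negative")


def read_dtraj(path) -> np.ndarray:
    """Read a discrete trajectory: one integer state per line."""
    d = np.loadtxt(path, dtype=int, comments="#", ndmin=1)
    if d.ndim != 1:
        raise ValueError(f"{path}: expected one state per line")
    return d


def write_dtraj(dtraj: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(dtraj, dtype=int), fmt="%d")


def rate_to_probability(k: float, t: float) -> float:
    """First-order transition probability p = 1 − exp(−k·t)."""
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    if t <= 0:
        raise ValueError("lag time must be positive")
    return float(-np.expm1(-k * t))


def estimate_transition_matrix(dtrajs: Sequence[np.ndarray], lag_steps: int,
                               pseudocount: float = 0.0,
                               symmetrize: bool = False,
                               lag_time: float | None = None) -> TransitionMatrix:
    """Count-based MSM estimation from integer state trajectories.

    Sliding-window transition counts at the requested lag are restricted to
    the largest strongly connected component and row-normalized.  State
    labels of the retained component are preserved in ``labels``.
    """
    if lag_steps < 1:
        raise ValueError("lag must be at least 1 step")
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    usable = [d for d in dtrajs if d.size > lag_steps]
    if not usable:
        raise ValueError("no trajectory longer than the lag")
    n = max(int(d.max()) for d in usable) + 1
    counts = np.zeros((n, n))
    for d in usable:
        np.add.at(counts, (d[:-lag_steps], d[lag_steps:]), 1.0)
    if symmetrize:
        counts = 0.5 * (counts + counts.T)
    # largest strongly connected component of the count graph
    graph = coo_matrix(counts)
    n_comp, assignment = connected_components(graph, directed=True,
                                              connection="strong")
    visited = np.unique(np.concatenate(usable)).astype(int)
    sizes = np.bincount(assignment[visited], minlength=n_comp)
    comp = int(np.argmax(sizes))
    keep = np.flatnonzero(assignment == comp)
    if keep.size == 0:
        raise ValueError("no connected set of states")
    sub = counts[np.ix_(keep, keep)] + pseudocount
    rows = sub.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("state with no outgoing counts in connected component")
    return TransitionMatrix(sub / rows[:, None],
                            lag=float(lag_time if lag_time is not None else lag_steps),
                            labels=[int(k) for k in keep])


def propagate(T: TransitionMatrix, p0: np.ndarray, duration: float) -> np.ndarray:
    """Propagate a population vector: p(t) = p0 · T^(duration/lag)."""
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (T.n_states,):
        raise ValueError("population vector dimension mismatch")
    steps_f = duration / T.lag
    steps = int(round(steps_f))
    if abs(steps_f - steps) > 1e-9:
        warnings.warn(
            f"duration is not a lag multiple; rounding {steps_f:g} to {steps} steps")
    return p0 @ np.linalg.matrix_power(T.matrix, steps)


def stationary_distribution(T: TransitionMatrix) -> np.ndarray:
    """Left Perron eigenvector of the transition matrix, normalized."""
    vals, vecs = scipy.linalg.eig(T.matrix, left=True, right=False)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TICAResult:
    components: np.ndarray      # (n_features, n_components), columns ordered
    eigenvalues: np.ndarray
    timescales: np.ndarray
    mean: np.ndarray
    lag: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components


def tica_decompose(trajs: Sequence[np.ndarray], lag_steps: int,
                   n_components: int | None = None,
                   regularization: float = 1e-6) -> TICAResult:
    """Time-lagged independent component analysis.

    Solves the symmetrized generalized eigenproblem
    C(τ) v = λ (C(0) + εI) v on mean-free features; components are ordered
    by decreasing eigenvalue and implied timescales are −τ/ln λ.
    """
    trajs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trajs]
    trajs = [t.T if t.shape[0] == 1 else t for t in trajs]
    usable = [t for t in trajs if t.shape[0] > lag_steps]
    if not usable:
        raise ValueError("no trajectory longer than the lag")
    mean = np.concatenate(usable).mean(axis=0)
    nf = usable[0].shape[1]
    c0 = np.zeros((nf, nf))
    ct = np.zeros((nf, nf))
    n_pairs = 0
    for t in usable:
        x = t - mean
        a, b = x[:-lag_steps], x[lag_steps:]
        c0 += a.T @ a + b.T @ b
        ct += a.T @ b
        n_pairs += a.shape[0]
    c0 /= 2.0 * n_pairs
    ct = 0.5 * (ct + ct.T) / n_pairs
    vals, vecs = scipy.linalg.eigh(ct, c0 + regularization * np.eye(nf))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.any(vals >= 1.0):
        warnings.warn("tICA eigenvalues >= 1 clamped (numerical)")
        vals = np.minimum(vals, 1.0 - 1e-12)
    if n_components is not None:
        vals, vecs = vals[:n_components], vecs[:, :n_components]
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(vals > 0, -float(lag_steps) / np.log(vals), 0.0)
    return TICAResult(components=vecs, eigenvalues=vals, timescales=ts,
                      mean=mean, lag=lag_steps)


# ---------------------------------------------------------------------------
# k-centers clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KCentersResult:
    labels: np.ndarray
    center_indices: np.ndarray
    centers: np.ndarray
    covering_radius: float


def kcenters_cluster(X: np.ndarray, k: int, seed: int = 0) -> KCentersResult:
    """Greedy (Gonzalez) k-centers clustering with Euclidean metric.

    The first center is a seeded-random data point; every subsequent center
    is the point farthest from the current center set.  The covering radius
    is at most twice the optimal one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError("k exceeds the number of points")
    rng = np.random.default_rng(seed)
    centers = [int(rng.integers(n))]
    dmin = np.linalg.norm(X - X[centers[0]], axis=1)
    labels = np.zeros(n, dtype=int)
    for c in range(1, k):
        nxt = int(np.argmax(dmin))
        centers.append(nxt)
        d = np.linalg.norm(X - X[nxt], axis=1)
        closer = d < dmin
        labels[closer] = c
        dmin = np.where(closer, d, dmin)
    idx = np.array(centers)
    return KCentersResult(labels=labels, center_indices=idx, centers=X[idx],
                          covering_radius=float(dmin.max()))


# ---------------------------------------------------------------------------
# cis/trans regime combination
# ---------------------------------------------------------------------------

def _mean_neighbor_rmsd(T: np.ndarray, structures: Sequence[Structure],
                        state: int, atom_selection) -> float:
    neighbors = [j for j in range(T.shape[0])
                 if j != state and T[state, j] > 0]
    if not neighbors:
        return np.inf
    return float(np.mean([
        rmsd_superposed(structures[state], structures[j], atom_selection)
        for j in neighbors]))


def derive_isomer_pairs(T_cis: TransitionMatrix, T_trans: TransitionMatrix,
                        structures_cis: Sequence[Structure],
                        structures_trans: Sequence[Structure],
                        atom_selection=None) -> list[tuple[int, int]]:
    """Pair each trans state with its argmin-RMSD cis state, then filter.

    A pair is retained only if its trans-cis RMSD is below the mean RMSD of
    the trans state to its directly connected trans neighbors AND below the
    same quantity for the cis state.  Ties in the argmin are broken by the
    lowest cis index.  States with no neighbors impose no constraint.
    """
    pairs: list[tuple[int, int]] = []
    for jt, st in enumerate(structures_trans):
        rmsds = np.array([rmsd_superposed(st, sc, atom_selection)
                          for sc in structures_cis])
        ic = int(np.argmin(rmsds))   # argmin takes the lowest index on ties
        r_pair = rmsds[ic]
        thr_trans = _mean_neighbor_rmsd(T_trans.matrix, structures_trans,
                                        jt, atom_selection)
        thr_cis = _mean_neighbor_rmsd(T_cis.matrix, structures_cis,
                                      ic, atom_selection)
        if r_pair < thr_trans and r_pair < thr_cis:
            pairs.append((jt, ic))
    return pairs


def combine_isomer_models(T_cis: TransitionMatrix, T_trans: TransitionMatrix,
                          coupling: IsomerCoupling,
                          structures_cis: Sequence[Structure] | None = None,
                          structures_trans: Sequence[Structure] | None = None,
                          atom_selection=None) -> TransitionMatrix:
    """Assemble the (n+m) x (n+m) combined cis/trans transition matrix.

    The cis block occupies indices [0, n) and the trans block [n, n+m).
    Retained pairs receive the symmetric off-diagonal-block probability
    p = 1 − exp(−k·lag) in both directions, with the diagonal absorbing the
    transferred mass to restore row stochasticity (falling back to whole-row
    rescaling if a diagonal entry would go negative).
    """
    if abs(T_cis.lag - T_trans.lag) > 1e-12 * max(T_cis.lag, T_trans.lag):
        raise ValueError("lag times of the two regimes differ")
    lag = T_cis.lag
    p = rate_to_probability(coupling.k, lag)
    if coupling.k * lag >= 1.0:
        warnings.warn("k·t >= 1: transition-probability interpretation is "
                      "questionable at this lag")
    pairs = coupling.pairs
    if pairs is None:
        if structures_cis is None or structures_trans is None:
            raise ValueError("structures required to derive isomer pairs")
        pairs = derive_isomer_pairs(T_cis, T_trans, structures_cis,
                                    structures_trans, atom_selection)
    n, m = T_cis.n_states, T_trans.n_states
    for jt, ic in pairs:
        if not (0 <= jt < m and 0 <= ic < n):
            raise ValueError(f"pair ({jt}, {ic}) references invalid states")
    full = np.zeros((n + m, n + m))
    full[:n, :n] = T_cis.matrix
    full[n:, n:] = T_trans.matrix
    if p > 0:
        off: dict[int, float] = {}
        for jt, ic in pairs:
            full[ic, n + jt] += p
            full[n + jt, ic] += p
            off[ic] = off.get(ic, 0.0) + p
            off[n + jt] = off.get(n + jt, 0.0) + p
        for row, mass in off.items():
            if full[row, row] >= mass:
                full[row, row] -= mass
            else:
                # minimal fallback: rescale the original row mass instead
                block = slice(0, n) if row < n else slice(n, n + m)
                orig_block = full[row, block].copy()
                orig_block *= (1.0 - mass) / orig_block.sum()
                full[row, block] = orig_block
    labels = [("cis", lab) for lab in T_cis.labels] + \
             [("trans", lab) for lab in T_trans.labels]
    return TransitionMatrix(full, lag=lag, labels=labels)
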