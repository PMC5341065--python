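"""Maximum-entropy-regularized ensemble reweighting against SAXS data.

The objective is G(w) = χ²(Σ_k w_k I_k, I_exp) + θ Σ_k w_k ln(w_k / w⁰_k),
minimized over the weight simplex by Metropolis simulated annealing.  χ²
includes the optimal scale/offset fit at every evaluation.  All stochastic
entry points take explicit seeds; there is no global random state.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .saxs_forward import SAXSProfile, chi_squared, fit_scale_offset

__all__ = [
    "EnsembleWeights",
    "RefinementConfig",
    "RefinementResult",
    "ensemble_profile",
    "relative_entropy",
    "objective_G",
    "anneal_refine",
    "theta_scan",
    "stability_check",
    "ablate_and_refine",
]

_SIMPLEX_TOL = 1e-10


@dataclasses.dataclass
class EnsembleWeights:
    """Normalized state populations together with their prior."""

    weights: np.ndarray
    prior: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        for name, v in (("weights", self.weights), ("prior", self.prior)):
            if v.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            if abs(v.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError(f"{name} must sum to 1 within {_SIMPLEX_TOL}")
        if self.weights.shape != self.prior.shape:
            raise ValueError("weights and prior length mismatch")

    @property
    def n_states(self) -> int:
        return self.weights.size

    @classmethod
    def uniform(cls, n: int) -> "EnsembleWeights":
        w = np.full(n, 1.0 / n)
        return cls(w, w.copy())

    @classmethod
    def from_prior(cls, prior: np.ndarray) -> "EnsembleWeights":
        prior = np.asarray(prior, dtype=float)
        return cls(prior.copy(), prior)


@dataclasses.dataclass
class RefinementConfig:
    theta: float = 0.0
    initial_temperature: float | None = None   # None: calibrated to ~50% accept
    cooling: float = 0.95
    max_sweeps: int = 2000
    move_scale: float = 0.3
    seed: int = 0
    tol: float = 1e-10
    patience: int = 50
    # moves with |ΔG| below this carry no information; rejecting them stops
    # diffusion along directions the data does not constrain
    gain_floor: float = 1e-9
    # at θ = 0 the minimizer of G is not unique along directions the data
    # does not constrain; move decisions then add an infinitesimal entropy
    # penalty (the θ → 0⁺ limit), so returned weights are the max-ent
    # member of the χ²-minimizing set.  None: auto-scale; 0: disable.
    tie_break_theta: float | None = None

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must lie in (0, 1)")


@dataclasses.dataclass
class RefinementResult:
    weights: EnsembleWeights
    G: float
    chi2: float
    penalty: float
    trace: np.ndarray          # best G after each sweep
    seed: int
    n_sweeps: int
    theta: float


def _profile_matrix(profiles: Sequence[SAXSProfile]) -> tuple[np.ndarray, np.ndarray]:
    q0 = profiles[0].q
    for p in profiles[1:]:
        if p.q.shape != q0.shape or not np.allclose(p.q, q0):
            raise ValueError("per-state profiles must share a common q grid")
    return q0, np.array([p.intensity for p in profiles])


def ensemble_profile(profiles: Sequence[SAXSProfile],
                     w: EnsembleWeights | np.ndarray) -> SAXSProfile:
    """Population-weighted average profile I_ens(q) = Σ_k w_k I_k(q)."""
    wv = w.weights if isinstance(w, EnsembleWeights) else np.asarray(w, float)
    if len(profiles) != wv.size:
        raise ValueError("profile count does not match weight count")
    q, A = _profile_matrix(profiles)
    return SAXSProfile(q, wv @ A)


def relative_entropy(w: np.ndarray, w0: np.ndarray) -> float:
    """Σ_k w_k ln(w_k / w⁰_k) with the 0·ln 0 := 0 convention."""
    w = np.asarray(w, float)
    w0 = np.asarray(w0, float)
    live = w > 0
    if np.any(w0[live] == 0):
        raise ValueError("state with zero prior carries weight: infinite penalty")
    return float(np.sum(w[live] * np.log(w[live] / w0[live])))


def objective_G(w: EnsembleWeights, profiles: Sequence[SAXSProfile],
                exp: SAXSProfile, theta: float) -> tuple[float, float, float]:
    """Evaluate (G, χ², penalty) at the given weights."""
    chi2 = chi_squared(ensemble_profile(profiles, w), exp)
    pen = relative_entropy(w.weights, w.prior)
    return chi2 + theta * pen, chi2, pen


class _Objective:
    """Fast G evaluation on a fixed q grid (precomputed profile matrix)."""

    def __init__(self, profiles, exp: SAXSProfile, prior: np.ndarray, theta: float):
        if exp.sigma is None:
            raise ValueError("experimental profile must carry uncertainties")
        if np.any(exp.sigma == 0):
            raise ValueError("experimental sigma contains zeros")
        q, A = _profile_matrix(profiles)
        if q.shape == exp.q.shape and np.allclose(q, exp.q):
            self.A = A
        else:
            self.A = np.array([
                SAXSProfile(q, row).interpolated(exp.q).intensity for row in A])
        self.i_exp = exp.intensity
        self.w_sig = 1.0 / exp.sigma ** 2
        self.prior = prior
        self.theta = theta
        sw = self.w_sig.sum()
        self._sw = sw
        self._my = (self.w_sig * self.i_exp).sum() / sw

    def chi2(self, w: np.ndarray) -> float:
        i_sim = w @ self.A
        ws = self.w_sig
        mx = (ws * i_sim).sum() / self._sw
        dx = i_sim - mx
        vxx = (ws * dx * dx).sum()
        if vxx <= 1e-30:
            c = 1.0
        else:
            c = (ws * dx * (self.i_exp - self._my)).sum() / vxx
        f = self._my - c * mx
        resid = c * i_sim + f - self.i_exp
        return float(np.mean(ws * resid * resid))

    def penalty(self, w: np.ndarray) -> float:
        return relative_entropy(w, self.prior)

    def G(self, w: np.ndarray) -> float:
        return self.chi2(w) + self.theta * self.penalty(w)


def anneal_refine(prior: EnsembleWeights | np.ndarray,
                  profiles: Sequence[SAXSProfile], exp: SAXSProfile,
                  cfg: RefinementConfig) -> RefinementResult:
    """Minimize G over the weight simplex by simulated annealing.

    Moves multiply one uniformly chosen weight by exp(δ), δ ~ N(0, s²),
    and renormalize; the move scale shrinks with the temperature so the
    search refines as it cools.  Returns the best weights ever visited.
    """
    if isinstance(prior, EnsembleWeights):
        w0 = prior.prior
        w_start = prior.weights
    else:
        w0 = np.asarray(prior, dtype=float)
        w_start = w0.copy()
    n = w0.size
    if n < 2:
        raise ValueError("refinement requires at least 2 states")
    obj = _Objective(profiles, exp, w0, cfg.theta)
    if cfg.theta == 0:
        tie = cfg.tie_break_theta
        if tie is None:
            tie = 0.01 * max(obj.chi2(w_start), 1e-8)
        obj.theta = tie
    rng = np.random.default_rng(cfg.seed)

    w = w_start.copy()
    g = obj.G(w)
    if not np.isfinite(g):
        raise ValueError("objective is non-finite at the starting weights")

    # calibrate T0 so that roughly half of initial moves would be accepted
    if cfg.initial_temperature is None:
        deltas = []
        for _ in range(64):
            i = int(rng.integers(n))
            wt = w.copy()
            wt[i] *= np.exp(rng.normal(0.0, cfg.move_scale))
            wt /= wt.sum()
            deltas.append(abs(obj.G(wt) - g))
        med = float(np.median(deltas))
        t0 = max(med, 1e-12) / np.log(2.0)
    else:
        t0 = cfg.initial_temperature

    best_w, best_g = w.copy(), g
    trace = []
    temp = t0
    stall = 0
    sweeps_done = 0
    for sweep in range(cfg.max_sweeps):
        scale = cfg.move_scale * max(np.sqrt(temp / t0), 0.02)
        for _ in range(n):
            i = int(rng.integers(n))
            delta = rng.normal(0.0, scale)
            wt = w * 1.0
            wt[i] *= np.exp(delta)
            wt /= wt.sum()
            gt = obj.G(wt)
            dg = gt - g
            if dg < -cfg.gain_floor or (
                    dg > cfg.gain_floor
                    and rng.random() < np.exp(-dg / max(temp, 1e-300))):
                w, g = wt, gt
                if g < best_g:
                    best_g, best_w = g, wt.copy()
        improvement = trace[-1] - best_g if trace else np.inf
        trace.append(best_g)
        sweeps_done = sweep + 1
        stall = stall + 1 if improvement < cfg.tol else 0
        if stall >= cfg.patience:
            break
        temp *= cfg.cooling

    # greedy quench: zero-temperature sweeps with a shrinking move scale
    # polish the best-visited weights
    w, g = best_w.copy(), best_g
    scale = cfg.move_scale
    while scale > 1e-3:
        stalled = 0
        for _ in range(60):
            g_before = g
            for _ in range(n):
                i = int(rng.integers(n))
                wt = w * 1.0
                wt[i] *= np.exp(rng.normal(0.0, scale))
                wt /= wt.sum()
                gt = obj.G(wt)
                if gt < g - cfg.gain_floor:
                    w, g = wt, gt
            trace.append(g)
            sweeps_done += 1
            stalled = stalled + 1 if g_before - g < cfg.tol else 0
            if stalled >= 5:
                break
        scale *= 0.5
    if g < best_g:
        best_g, best_w = g, w

    chi2 = obj.chi2(best_w)
    pen = obj.penalty(best_w)
    return RefinementResult(
        weights=EnsembleWeights(best_w, w0.copy()),
        G=chi2 + cfg.theta * pen, chi2=chi2, penalty=pen,
        trace=np.array(trace), seed=cfg.seed, n_sweeps=sweeps_done,
        theta=cfg.theta)


def theta_scan(prior, profiles, exp, thetas: Sequence[float],
               cfg: RefinementConfig) -> dict:
    """Refine once per θ and tabulate converged χ² and penalty.

    Returns a dict with the table and an elbow suggestion (largest discrete
    curvature of χ² on the grid); the final choice of θ stays with the user.
    """
    thetas = list(thetas)
    if any(t < 0 for t in thetas) or sorted(thetas) != thetas:
        raise ValueError("theta grid must be non-negative and sorted")
    rows = []
    for i, theta in enumerate(thetas):
        sub = dataclasses.replace(cfg, theta=float(theta),
                                  seed=int(np.random.SeedSequence(
                                      [cfg.seed, i]).generate_state(1)[0]))
        res = anneal_refine(prior, profiles, exp, sub)
        rows.append({"theta": float(theta), "chi2": res.chi2,
                     "penalty": res.penalty, "G": res.G})
    chi2s = np.array([r["chi2"] for r in rows])
    elbow = None
    if len(thetas) >= 3:
        curv = chi2s[2:] - 2 * chi2s[1:-1] + chi2s[:-2]
        elbow = float(thetas[1 + int(np.argmax(curv))])
    return {"table": rows, "elbow_theta": elbow}


def stability_check(prior, profiles, exp, cfg: RefinementConfig,
                    n_runs: int = 20, seeds=None) -> dict:
    """Run independent refinements and quantify profile spread.

    Spread is the per-q standard deviation across converged ensemble
    profiles, reported as a fraction of the experimental σ.  Per-run seeds
    default to distinct values derived from ``cfg.seed``.
    """
    if n_runs < 2:
        raise ValueError("stability check requires at least 2 runs")
    if seeds is None:
        seeds = [int(np.random.SeedSequence([cfg.seed, 7919, r])
                     .generate_state(1)[0]) for r in range(n_runs)]
    elif len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    results = []
    for r in range(n_runs):
        sub = dataclasses.replace(cfg, seed=int(seeds[r]))
        results.append(anneal_refine(prior, profiles, exp, sub))
    prof = np.array([
        ensemble_profile(profiles, res.weights).interpolated(exp.q).intensity
        for res in results])
    std = prof.std(axis=0, ddof=1)
    frac = std / exp.sigma
    return {
        "results": results,
        "profile_std": std,
        "spread_fraction": frac,
        "max_spread_fraction": float(frac.max()),
        "mean_spread_fraction": float(frac.mean()),
    }


def ablate_and_refine(prior, profiles, exp, cfg: RefinementConfig,
                      remove_mask: np.ndarray) -> dict:
    """Remove masked states, renormalize the prior, and re-refine.

    Returns the ablated result, the unablated reference refinement run with
    the same configuration, and their χ² difference.
    """
    if isinstance(prior, EnsembleWeights):
        w0 = prior.prior
    else:
        w0 = np.asarray(prior, dtype=float)
    remove_mask = np.asarray(remove_mask, dtype=bool)
    if remove_mask.shape != w0.shape:
        raise ValueError("mask length mismatch")
    keep = ~remove_mask
    if keep.sum() < 2:
        raise ValueError("ablation must retain at least 2 states")
    full = anneal_refine(EnsembleWeights.from_prior(w0), profiles, exp, cfg)
    if not remove_mask.any():
        return {"ablated": full, "full": full, "delta_chi2": 0.0,
                "kept_states": np.flatnonzero(keep)}
    sub_prior = w0[keep] / w0[keep].sum()
    sub_profiles = [p for p, k in zip(profiles, keep) if k]
    ablated = anneal_refine(EnsembleWeights.from_prior(sub_prior),
                            sub_profiles, exp, cfg)
    return {"ablated": ablated, "full": full,
            "delta_chi2": ablated.chi2 - full.chi2,
            "kept_states": np.flatnonzero(keep)}
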