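"""Three-step excited-state inference pipeline.

Step 1 refines a uniform prior against the unfolded-state SAXS profile
(E_U); step 2 propagates those populations with the kinetic model to the
requested time point (E_MSM); step 3 refines E_MSM against the refolded
SAXS profile (E_SAXS).  Every stage seed derives from one master seed, and
the report records seeds, thetas, and input file hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np

from .core_structures import contact_map, read_pdb
from .ensemble_analysis import difference_map, weighted_contact_density
from .eros_refine import (EnsembleWeights, RefinementConfig, anneal_refine,
                          ensemble_profile)
from .msm_kinetics import TransitionMatrix, propagate
from .saxs_forward import chi_squared, read_profile

__all__ = ["PipelineConfig", "PipelineResult", "run_inference"]


@dataclasses.dataclass
class PipelineConfig:
    profiles_dir: str
    exp_unfolded: str
    exp_refolded: str
    transition_matrix: str
    theta_unfolded: float
    theta_excited: float
    duration: float
    out_dir: str
    seed: int = 0
    structures_dir: str | None = None
    max_sweeps: int = 1000
    cooling: float = 0.95
    move_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("propagation duration must be positive")
        for attr in ("profiles_dir", "exp_unfolded", "exp_refolded",
                     "transition_matrix"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


@dataclasses.dataclass
class PipelineResult:
    e_u: EnsembleWeights
    e_msm: np.ndarray
    e_saxs: EnsembleWeights
    chi2_unfolded: float
    chi2_refolded: float
    report: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_profiles(directory):
    paths = sorted(Path(directory).glob("*.dat"))
    if not paths:
        raise FileNotFoundError(f"no .dat profiles in {directory}")
    return paths, [read_profile(p) for p in paths]


def run_inference(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    profile_paths, profiles = _load_profiles(cfg.profiles_dir)
    exp_u = read_profile(cfg.exp_unfolded)
    exp_r = read_profile(cfg.exp_refolded)
    tmat = TransitionMatrix.read(cfg.transition_matrix)
    n = len(profiles)
    if tmat.n_states != n:
        raise ValueError(
            f"transition matrix has {tmat.n_states} states, {n} profiles given")

    seed_u, seed_e = (int(s.generate_state(1)[0])
                      for s in np.random.SeedSequence(cfg.seed).spawn(2))
    base = dict(max_sweeps=cfg.max_sweeps, cooling=cfg.cooling,
                move_scale=cfg.move_scale)

    # (1) refine uniform prior against the unfolded-state profile
    res_u = anneal_refine(
        EnsembleWeights.uniform(n), profiles, exp_u,
        RefinementConfig(theta=cfg.theta_unfolded, seed=seed_u, **base))
    # (2) propagate to the requested time point
    e_msm = propagate(tmat, res_u.weights.weights, cfg.duration)
    # (3) refine the propagated prior against the refolded profile
    res_e = anneal_refine(
        EnsembleWeights.from_prior(e_msm), profiles, exp_r,
        RefinementConfig(theta=cfg.theta_excited, seed=seed_e, **base))

    report = {
        "seed": cfg.seed,
        "stage_seeds": {"refine_unfolded": seed_u, "refine_excited": seed_e},
        "theta": {"unfolded": cfg.theta_unfolded, "excited": cfg.theta_excited},
        "duration": cfg.duration,
        "lag": tmat.lag,
        "n_states": n,
        "chi2": {"unfolded": res_u.chi2, "refolded": res_e.chi2,
                 "prior_vs_refolded": chi_squared(
                     ensemble_profile(profiles, e_msm), exp_r)},
        "inputs": {
            "profiles": [{"path": str(p), "sha256": _sha256(p)}
                         for p in profile_paths],
            "exp_unfolded": {"path": cfg.exp_unfolded,
                             "sha256": _sha256(cfg.exp_unfolded)},
            "exp_refolded": {"path": cfg.exp_refolded,
                             "sha256": _sha256(cfg.exp_refolded)},
            "transition_matrix": {"path": cfg.transition_matrix,
                                  "sha256": _sha256(cfg.transition_matrix)},
        },
        "weights": {
            "E_U": res_u.weights.weights.tolist(),
            "E_MSM": e_msm.tolist(),
            "E_SAXS": res_e.weights.weights.tolist(),
        },
    }

    if cfg.structures_dir is not None:
        pdbs = sorted(Path(cfg.structures_dir).glob("*.pdb"))
        if len(pdbs) != n:
            raise ValueError(
                f"{len(pdbs)} structures for {n} states in {cfg.structures_dir}")
        maps = [contact_map(read_pdb(p)) for p in pdbs]
        dens_msm = weighted_contact_density(maps, e_msm)
        dens_saxs = weighted_contact_density(maps, res_e.weights.weights)
        dens_msm.write(out / "contact_density_EMSM.txt")
        dens_saxs.write(out / "contact_density_ESAXS.txt")
        np.savetxt(out / "contact_difference_ESAXS_minus_EMSM.txt",
                   difference_map(dens_saxs, dens_msm), fmt="%.6g")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / "weights.tsv", "w") as fh:
        fh.write("# state\tE_U\tE_MSM\tE_SAXS\n")
        for k in range(n):
            fh.write(f"{k}\t{res_u.weights.weights[k]:.10e}\t"
                     f"{e_msm[k]:.10e}\t{res_e.weights.weights[k]:.10e}\n")

    return PipelineResult(e_u=res_u.weights, e_msm=e_msm,
                          e_saxs=res_e.weights,
                          chi2_unfolded=res_u.chi2, chi2_refolded=res_e.chi2,
                          report=report)
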