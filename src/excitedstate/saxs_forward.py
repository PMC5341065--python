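"""Debye-equation SAXS prediction, Guinier analysis, and profile fitting.

The forward model is deliberately minimal: tabulated atomic form factors
with implicit hydrogens folded in, no hydration shell, no excluded-volume
term.  Absolute agreement with hydration-aware predictors is therefore not
expected; relative and ensemble-level behavior is the target.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .chemdata import form_factor, hydrogen_count
from .core_structures import Structure

__all__ = [
    "SAXSProfile",
    "ScaleOffsetFit",
    "read_profile",
    "write_profile",
    "debye_profile",
    "guinier_rg",
    "fit_scale_offset",
    "chi_squared",
]


@dataclasses.dataclass
class SAXSProfile:
    """Scattering intensity I(q) on a strictly increasing q grid (Å⁻¹).

    ``sigma`` holds per-point experimental uncertainties and may be None
    for simulated profiles.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    @property
    def n_points(self) -> int:
        return self.q.size

    def interpolated(self, q_new: np.ndarray) -> "SAXSProfile":
        """Linear interpolation onto a new grid; extrapolation is an error."""
        q_new = np.asarray(q_new, dtype=float)
        if q_new.min() < self.q.min() - 1e-12 or q_new.max() > self.q.max() + 1e-12:
            raise ValueError("interpolation grid extends beyond profile range")
        i_new = np.interp(q_new, self.q, self.intensity)
        s_new = None if self.sigma is None else np.interp(q_new, self.q, self.sigma)
        return SAXSProfile(q_new, i_new, s_new)


def read_profile(path) -> SAXSProfile:
    """Read a 3-column (q, I, σ) or 2-column text profile; '#' comments."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"expected at least 2 columns in {path}")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSProfile(data[:, 0], data[:, 1], sigma)


def write_profile(p: SAXSProfile, path, header: str = "") -> None:
    cols = [p.q, p.intensity] + ([] if p.sigma is None else [p.sigma])
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# q[1/A]  I  " + ("sigma\n" if p.sigma is not None else "\n"))
        np.savetxt(fh, np.column_stack(cols), fmt="%.8e")


def _atomic_f(s: Structure, q: np.ndarray, fold_hydrogens: bool) -> np.ndarray:
    """(n_atoms, n_q) per-atom form factors."""
    f = np.empty((s.n_atoms, q.size))
    for k in range(s.n_atoms):
        nh = hydrogen_count(s.res_names[k], s.atom_names[k]) if fold_hydrogens else 0
        f[k] = form_factor(s.elements[k], q, n_hydrogens=nh)
    return f


def debye_profile(s: Structure, q_grid: np.ndarray,
                  fold_hydrogens: bool = True) -> SAXSProfile:
    """Orientationally averaged scattering of a rigid atom set.

    I(q) = Σ_i Σ_j f_i(q) f_j(q) sinc(q d_ij), evaluated exactly via the
    full double sum (no distance binning).
    """
    q = np.asarray(q_grid, dtype=float)
    f = _atomic_f(s, q, fold_hydrogens)
    d = squareform(pdist(s.coords)) if s.n_atoms > 1 else np.zeros((1, 1))
    intensity = np.empty(q.size)
    for iq, qv in enumerate(q):
        # np.sinc(x) = sin(pi x)/(pi x); handles qd -> 0 exactly
        sinc = np.sinc(qv * d / np.pi)
        fq = f[:, iq]
        intensity[iq] = fq @ sinc @ fq
    return SAXSProfile(q, intensity)


@dataclasses.dataclass
class GuinierFit:
    rg: float
    i0: float
    q_max: float
    n_points: int


def guinier_rg(p: SAXSProfile, q_max_rg: float = 1.3, min_points: int = 5,
               max_iter: int = 20) -> GuinierFit:
    """Radius of gyration from an iterated Guinier fit of ln I vs q².

    The fit window [q_min, q_max] is shrunk (or grown) until
    q_max · Rg ≤ q_max_rg holds self-consistently.
    """
    q, i = p.q, p.intensity
    hi = max(min_points, min(q.size, 10))
    rg = i0 = None
    for _ in range(max_iter):
        qs, is_ = q[:hi], i[:hi]
        if np.any(is_ <= 0):
            raise ValueError("non-positive intensities in Guinier region")
        slope, intercept = np.polyfit(qs ** 2, np.log(is_), 1)
        if slope >= 0:
            raise ValueError("non-decreasing Guinier region; no Rg")
        rg = float(np.sqrt(-3.0 * slope))
        i0 = float(np.exp(intercept))
        hi_new = int(np.searchsorted(q, q_max_rg / rg, side="right"))
        hi_new = max(hi_new, min_points)
        if hi_new > q.size:
            hi_new = q.size
        if hi_new == hi:
            break
        hi = hi_new
    if hi < min_points or q.size < min_points:
        raise ValueError("Guinier region collapsed below minimum point count")
    return GuinierFit(rg=rg, i0=i0, q_max=float(q[hi - 1]), n_points=hi)


@dataclasses.dataclass
class ScaleOffsetFit:
    """Affine map c·I_sim + f fitted to an experimental profile."""

    c: float
    f: float
    chi2: float


def _prepare(sim: SAXSProfile, exp: SAXSProfile):
    if exp.sigma is None:
        raise ValueError("experimental profile must carry uncertainties")
    if np.any(exp.sigma == 0):
        raise ValueError("experimental sigma contains zeros")
    if sim.q.shape == exp.q.shape and np.allclose(sim.q, exp.q):
        i_sim = sim.intensity
    else:
        i_sim = sim.interpolated(exp.q).intensity
    return i_sim, exp.intensity, exp.sigma


def fit_scale_offset(sim: SAXSProfile, exp: SAXSProfile) -> ScaleOffsetFit:
    """Weighted least-squares scale c and offset f (closed form).

    Degenerate (constant) simulated profiles fall back to c = 1 with an
    offset-only fit, with a warning.
    """
    i_sim, i_exp, sigma = _prepare(sim, exp)
    w = 1.0 / sigma ** 2
    sw = w.sum()
    mx = (w * i_sim).sum() / sw
    my = (w * i_exp).sum() / sw
    vxx = (w * (i_sim - mx) ** 2).sum()
    if vxx <= 1e-30 * max(1.0, my ** 2):
        warnings.warn("constant simulated profile; fitting offset only")
        c = 1.0
    else:
        c = float((w * (i_sim - mx) * (i_exp - my)).sum() / vxx)
        if c <= 0:
            warnings.warn("non-positive fitted scale; profiles anticorrelated")
    f = float(my - c * mx)
    resid = (c * i_sim + f - i_exp) / sigma
    chi2 = float(np.mean(resid ** 2))
    return ScaleOffsetFit(c=c, f=f, chi2=chi2)


def chi_squared(sim: SAXSProfile, exp: SAXSProfile,
                c: float | None = None, f: float | None = None) -> float:
    """Reduced χ² = (1/N_q) Σ [(c·I_sim + f − I_exp)/σ]².

    With c or f omitted, the optimal affine map is fitted first.
    """
    if c is None or f is None:
        fit = fit_scale_offset(sim, exp)
        c = fit.c if c is None else c
        f = fit.f if f is None else f
        if (c, f) == (fit.c, fit.f):
            return fit.chi2
    i_sim, i_exp, sigma = _prepare(sim, exp)
    resid = (c * i_sim + f - i_exp) / sigma
    return float(np.mean(resid ** 2))
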