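"""Inhomogeneous solubility-diffusion (ISD) permeability.

The membrane's local resistance to a permeant is::

    R(z) = exp(beta dG(z)) / D(z)          [ps/nm^2]

with beta = 1/(R_gas T) (free energies are molar).  The effective
resistivity is the integral across the membrane, and the permeability
coefficient its inverse::

    R_eff = integral_{z1}^{z2} R(z) dz     [ps/nm]
    P     = 1 / R_eff                      [nm/ps]  ->  x 1e5 = cm/s

Besides the gridded pipeline path, :func:`analytic_permeability` evaluates
the same integral on an analytic truth landscape with adaptive quadrature —
the reference the sampled pipeline is judged against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import integrate as _sint

from .constants import NM_PER_PS_TO_CM_PER_S, beta as _beta
from .diffusivity import DiffusivityProfile
from .landscapes import DiffusivityModel, EnergyLandscape
from .wham import PmfProfile

__all__ = [
    "ResistivityProfile",
    "PermeabilityResult",
    "resistivity_profile",
    "effective_resistivity",
    "permeability",
    "log_permeability",
    "analytic_permeability",
]


@dataclass(frozen=True)
class ResistivityProfile:
    """Local resistivity R(z) = exp(beta dG)/D on the PMF grid."""

    z_grid: np.ndarray       # nm
    R: np.ndarray            # ps/nm^2
    temperature: float       # K
    beta: float              # mol/kJ
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_grid, dtype=float)
        r = np.asarray(self.R, dtype=float)
        if z.shape != r.shape or z.ndim != 1:
            raise ValueError("z_grid and R must be matching 1-D arrays")
        m = (np.zeros(z.size, dtype=bool) if self.mask is None
             else np.asarray(self.mask, dtype=bool))
        if np.any(r[~m] <= 0):
            raise ValueError("resistivity must be positive on valid bins")
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "R", r)
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class PermeabilityResult:
    """Effective resistivity and permeability for one solute/membrane pair."""

    R_eff: float             # ps/nm
    P_nm_per_ps: float
    P_cm_per_s: float
    log10_P: float           # log10 of P in cm/s
    z1: float                # nm, integration bounds
    z2: float
    temperature: float = 310.0
    meta: dict = field(default_factory=dict)


def resistivity_profile(pmf: PmfProfile, diff: DiffusivityProfile,
                        temperature: float | None = None) -> ResistivityProfile:
    """Pointwise R(z) = exp(beta dG(z)) / D(z) on the shared grid.

    Requires a bulk-referenced PMF (otherwise the absolute scale of
    exp(beta dG) — and hence P — would be arbitrary) and a strictly positive
    diffusivity on an identical grid.  Masked PMF bins stay masked.
    """
    if pmf.reference != "bulk-zeroed":
        raise ValueError("PMF must be bulk-referenced before computing resistivity "
                         f"(reference={pmf.reference!r})")
    if temperature is None:
        temperature = float(pmf.meta.get("temperature_K", 310.0))
    if pmf.z_grid.shape != diff.z_grid.shape or not np.allclose(
            pmf.z_grid, diff.z_grid, atol=1e-9):
        raise ValueError("PMF and diffusivity grids are not aligned")
    if np.any(diff.D <= 0):
        raise ValueError("diffusivity must be strictly positive")
    b = _beta(temperature)
    with np.errstate(over="raise"):
        r = np.where(pmf.valid, np.exp(b * np.where(pmf.valid, pmf.dG, 0.0)) / diff.D,
                     np.nan)
    return ResistivityProfile(z_grid=pmf.z_grid, R=r, temperature=temperature,
                              beta=b, mask=pmf.mask.copy(),
                              meta={"pmf_smoothed": pmf.smoothed, "side": pmf.side})


def effective_resistivity(r: ResistivityProfile, z1: float, z2: float) -> float:
    """Trapezoidal integral of R over [z1, z2] (ps/nm).

    The bounds snap to the grid points inside [z1, z2]; masked bins inside
    the bounds are an error (no free energy may be invented there).
    """
    if z1 >= z2:
        raise ValueError(f"need z1 < z2, got [{z1}, {z2}]")
    grid = r.z_grid
    if z1 < grid[0] - 1e-9 or z2 > grid[-1] + 1e-9:
        raise ValueError(f"bounds [{z1}, {z2}] outside grid span "
                         f"[{grid[0]:.3f}, {grid[-1]:.3f}]")
    sel = (grid >= z1 - 1e-12) & (grid <= z2 + 1e-12)
    if sel.sum() < 2:
        raise ValueError("fewer than two grid points inside the bounds")
    if np.any(r.mask[sel]):
        raise ValueError("masked (unsampled) bins inside the integration bounds")
    return float(np.trapezoid(r.R[sel], grid[sel]))


def permeability(R_eff: float, z1: float = -2.2, z2: float = 2.2,
                 temperature: float = 310.0, meta: dict | None = None) -> PermeabilityResult:
    """Invert an effective resistivity (ps/nm) into a permeability.

    P = 1/R_eff in nm/ps; 1 nm/ps = 1e5 cm/s.
    """
    if R_eff <= 0:
        raise ValueError(f"R_eff must be positive, got {R_eff}")
    p_nm_ps = 1.0 / R_eff
    p_cm_s = p_nm_ps * NM_PER_PS_TO_CM_PER_S
    return PermeabilityResult(R_eff=float(R_eff), P_nm_per_ps=p_nm_ps,
                              P_cm_per_s=p_cm_s, log10_P=math.log10(p_cm_s),
                              z1=float(z1), z2=float(z2), temperature=temperature,
                              meta=meta or {})


def log_permeability(P_cm_per_s: float) -> float:
    """Base-10 log of a permeability in cm/s (round only at report time)."""
    if P_cm_per_s <= 0:
        raise ValueError(f"permeability must be positive, got {P_cm_per_s}")
    return math.log10(P_cm_per_s)


def analytic_permeability(landscape: EnergyLandscape, diff: DiffusivityModel,
                          z1: float, z2: float, temperature: float = 310.0,
                          bulk_region=None) -> PermeabilityResult:
    """ISD permeability of an analytic truth (dG, D) pair by adaptive quadrature.

    ``bulk_region`` (one interval or a list) optionally zero-references the
    truth profile the same way the estimated PMF is referenced, so truth and
    pipeline values share a convention.  Used as the oracle in end-to-end
    recovery checks.
    """
    if z1 >= z2:
        raise ValueError("need z1 < z2")
    b = _beta(temperature)
    shift = 0.0
    if bulk_region is not None:
        regions = ([bulk_region] if np.isscalar(bulk_region[0]) else list(bulk_region))
        vals = []
        for a, c in regions:
            zs = np.linspace(a, c, 101)
            vals.append(np.asarray(landscape.value(zs), dtype=float))
        shift = float(np.mean(np.concatenate(vals)))

    def integrand(z):
        return math.exp(b * (float(landscape.value(z)) - shift)) / float(diff.value(z))

    r_eff, _ = _sint.quad(integrand, z1, z2, limit=400)
    return permeability(r_eff, z1=z1, z2=z2, temperature=temperature,
                        meta={"source": "analytic-truth", "landscape": landscape.name})
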