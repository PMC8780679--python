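"""Analytic free-energy landscapes and diffusivity models.

These objects are the ground truth behind the synthetic umbrella-sampling
data: a free-energy profile ``dG(z)`` (kJ/mol) and a position-dependent
diffusion coefficient ``D(z)`` (nm^2/ps) along the bilayer normal ``z`` (nm).
The estimation pipeline (WHAM -> D(z) -> permeability) is validated by how
well it recovers them from simulated window trajectories.

All ``value``/``gradient`` callables are numpy ufunc-compatible: they accept
scalars or arrays and return the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np

__all__ = [
    "EnergyLandscape",
    "DiffusivityModel",
    "make_reference_landscape",
    "constant_diffusivity",
    "linear_diffusivity",
    "gaussian_dip_diffusivity",
    "DEFAULT_SUPPORT",
]

#: Default reaction-coordinate span, nm: bulk water to bulk water across the
#: bilayer, matching a ~4.4 nm sampled span.
DEFAULT_SUPPORT: Tuple[float, float] = (-2.2, 2.2)


@dataclass(frozen=True)
class EnergyLandscape:
    """Free-energy profile dG(z) with an exact analytic gradient.

    Parameters
    ----------
    name : str
        Preset label.
    value : callable
        dG(z) in kJ/mol.
    gradient : callable
        d(dG)/dz in kJ/mol/nm; must be the exact derivative of ``value``.
    support : (float, float)
        Interval of z (nm) on which the landscape is defined; the simulator
        reflects at these edges.
    bulk_edge : float or None
        If set, |z| >= bulk_edge is bulk water where dG(z) == 0 (to floating
        point) — the "bulk-flat" guarantee used for zero-referencing.
    """

    name: str
    value: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    support: Tuple[float, float] = DEFAULT_SUPPORT
    bulk_edge: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not lo < hi:
            raise ValueError(f"empty support {self.support}")


@dataclass(frozen=True)
class DiffusivityModel:
    """Position-dependent diffusion coefficient D(z) > 0 with its gradient.

    ``is_constant`` lets the simulator skip the spurious-drift term and
    precompute the noise amplitude.
    """

    name: str
    value: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    is_constant: bool = False
    support: Tuple[float, float] = DEFAULT_SUPPORT

    def validate_positive(self, n_check: int = 401) -> None:
        """Raise if D(z) <= 0 anywhere on a dense grid over the support."""
        zs = np.linspace(self.support[0], self.support[1], n_check)
        d = np.asarray(self.value(zs), dtype=float)
        if not np.all(np.isfinite(d)) or np.any(d <= 0.0):
            raise ValueError(f"diffusivity model {self.name!r} is not strictly positive "
                             f"on {self.support}")


def constant_diffusivity(d0: float, support: Tuple[float, float] = DEFAULT_SUPPORT) -> DiffusivityModel:
    """Uniform D(z) = d0 (nm^2/ps)."""
    if d0 <= 0:
        raise ValueError(f"D0 must be positive, got {d0}")
    return DiffusivityModel(
        name=f"constant(D0={d0})",
        value=lambda z: np.full_like(np.asarray(z, dtype=float), d0),
        gradient=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
        is_constant=True,
        support=support,
    )


def linear_diffusivity(d0: float, slope: float,
                       support: Tuple[float, float] = DEFAULT_SUPPORT) -> DiffusivityModel:
    """D(z) = d0 + slope*z, requiring positivity across the support."""
    lo, hi = support
    if min(d0 + slope * lo, d0 + slope * hi) <= 0:
        raise ValueError("linear diffusivity is non-positive inside the support")
    model = DiffusivityModel(
        name=f"linear(D0={d0},slope={slope})",
        value=lambda z: d0 + slope * np.asarray(z, dtype=float),
        gradient=lambda z: np.full_like(np.asarray(z, dtype=float), slope),
        is_constant=(slope == 0.0),
        support=support,
    )
    model.validate_positive()
    return model


def gaussian_dip_diffusivity(d0: float, dip_frac: float = 0.5, sigma: float = 0.8,
                             support: Tuple[float, float] = DEFAULT_SUPPORT) -> DiffusivityModel:
    """D(z) = d0*(1 - dip_frac*exp(-z^2/(2 sigma^2))).

    Mimics the slowdown of a solute inside the ordered acyl-chain region.
    """
    if not 0.0 <= dip_frac < 1.0:
        raise ValueError("dip_frac must be in [0, 1)")
    if d0 <= 0 or sigma <= 0:
        raise ValueError("D0 and sigma must be positive")

    def value(z):
        z = np.asarray(z, dtype=float)
        return d0 * (1.0 - dip_frac * np.exp(-z * z / (2.0 * sigma ** 2)))

    def gradient(z):
        z = np.asarray(z, dtype=float)
        return d0 * dip_frac * (z / sigma ** 2) * np.exp(-z * z / (2.0 * sigma ** 2))

    return DiffusivityModel(name=f"gaussian_dip(D0={d0},dip={dip_frac},sigma={sigma})",
                            value=value, gradient=gradient, support=support)


def _flat(support):
    return EnergyLandscape(
        name="flat",
        value=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
        gradient=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
        support=support,
        bulk_edge=0.0,
    )


def _square_barrier(height, width, steepness, support):
    lo, hi = support
    if width >= hi - lo:
        raise ValueError(f"barrier width {width} exceeds support span {hi - lo}")
    half = width / 2.0

    def value(z):
        z = np.asarray(z, dtype=float)
        return 0.5 * height * (np.tanh((z + half) / steepness)
                               - np.tanh((z - half) / steepness))

    def gradient(z):
        z = np.asarray(z, dtype=float)
        return 0.5 * height / steepness * (np.cosh((z + half) / steepness) ** -2
                                           - np.cosh((z - half) / steepness) ** -2)

    # tanh walls decay like exp(-2 d/steepness): below 1e-9 of the height
    # roughly 12 steepness lengths past the wall.
    edge = half + 12.0 * steepness
    bulk_edge = edge if edge < min(abs(lo), hi) else None
    return EnergyLandscape(name="square_barrier", value=value, gradient=gradient,
                           support=support, bulk_edge=bulk_edge)


def _gaussian_barrier(height, sigma, support):
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if 2 * sigma >= support[1] - support[0]:
        raise ValueError("barrier width exceeds support")

    def value(z):
        z = np.asarray(z, dtype=float)
        return height * np.exp(-z * z / (2.0 * sigma ** 2))

    def gradient(z):
        z = np.asarray(z, dtype=float)
        return -height * (z / sigma ** 2) * np.exp(-z * z / (2.0 * sigma ** 2))

    return EnergyLandscape(name="gaussian_barrier", value=value, gradient=gradient,
                           support=support, bulk_edge=None)


def _quartic_bump(z, center, width):
    u = (np.asarray(z, dtype=float) - center) / width
    return np.exp(-u ** 4)


def _quartic_bump_grad(z, center, width):
    u = (np.asarray(z, dtype=float) - center) / width
    return -4.0 * u ** 3 / width * np.exp(-u ** 4)


def _membrane_like(barrier, well_depth, well_pos, barrier_width, well_width, support):
    """Core barrier flanked by head-group wells; float-exactly 0 in bulk.

    Quartic-exponent Gaussians keep the profile C^1 while decaying fast
    enough that |z| >~ 2 nm is bulk-flat to double precision.
    """
    if barrier_width >= support[1] - support[0]:
        raise ValueError("barrier width exceeds support")
    if well_depth > 0:
        raise ValueError("well_depth is a depth: must be <= 0")

    def value(z):
        return (barrier * _quartic_bump(z, 0.0, barrier_width)
                + well_depth * (_quartic_bump(z, -well_pos, well_width)
                                + _quartic_bump(z, well_pos, well_width)))

    def gradient(z):
        return (barrier * _quartic_bump_grad(z, 0.0, barrier_width)
                + well_depth * (_quartic_bump_grad(z, -well_pos, well_width)
                                + _quartic_bump_grad(z, well_pos, well_width)))

    return EnergyLandscape(name="membrane_like", value=value, gradient=gradient,
                           support=support, bulk_edge=2.1)


_PRESETS = ("flat", "square_barrier", "gaussian_barrier", "membrane_like")


def make_reference_landscape(name: str, **params) -> Tuple[EnergyLandscape, DiffusivityModel]:
    """Build a named reference (dG(z), D(z)) pair on [-2.2, +2.2] nm.

    Parameters
    ----------
    name : {"flat", "square_barrier", "gaussian_barrier", "membrane_like"}
    **params
        ``D0`` (nm^2/ps, default 0.04) selects a constant diffusivity; pass
        ``diffusivity=<DiffusivityModel>`` to override with a position-
        dependent model.  Landscape shape parameters (all optional):

        - square_barrier: ``height`` (kJ/mol, 10), ``width`` (nm, 1.0),
          ``steepness`` (nm, 0.05 — tanh smoothing length so the gradient
          exists everywhere).
        - gaussian_barrier: ``height`` (10), ``sigma`` (nm, 0.5).
        - membrane_like: ``barrier`` (12), ``well_depth`` (-4),
          ``well_pos`` (1.3), ``barrier_width`` (0.45), ``well_width`` (0.3).

    Returns
    -------
    (EnergyLandscape, DiffusivityModel)
    """
    support = params.pop("support", DEFAULT_SUPPORT)
    diff = params.pop("diffusivity", None)
    d0 = params.pop("D0", 0.04)
    if diff is None:
        diff = constant_diffusivity(d0, support=support)
    diff.validate_positive()

    if name == "flat":
        land = _flat(support)
    elif name == "square_barrier":
        land = _square_barrier(params.pop("height", 10.0), params.pop("width", 1.0),
                               params.pop("steepness", 0.05), support)
    elif name == "gaussian_barrier":
        land = _gaussian_barrier(params.pop("height", 10.0), params.pop("sigma", 0.5),
                                 support)
    elif name == "membrane_like":
        land = _membrane_like(params.pop("barrier", 12.0), params.pop("well_depth", -4.0),
                              params.pop("well_pos", 1.3), params.pop("barrier_width", 0.45),
                              params.pop("well_width", 0.3), support)
    else:
        raise ValueError(f"unknown landscape {name!r}; choose from {_PRESETS}")
    if params:
        raise TypeError(f"unused landscape parameters: {sorted(params)}")
    return land, diff
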