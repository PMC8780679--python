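"""Overdamped Langevin dynamics in umbrella windows.

Stands in for the MD engine: the downstream analysis consumes only the
reaction-coordinate time series z(t) of each harmonically restrained window,
so a 1-D Brownian dynamics integrator with the correct stationary law and
local mobility exercises the entire pipeline.

The Ito SDE integrated by Euler-Maruyama is::

    dz = [ -beta * D(z) * (dG'(z) + k (z - c)) + D'(z) ] dt
         + sqrt(2 D(z) dt) * xi,    xi ~ N(0, 1)

The D'(z) term is the spurious drift required so the stationary density is
proportional to exp(-beta (dG(z) + w(z))) even when D depends on position.
Trajectories reflect at the support edges (bulk water boundaries).

Windows are integrated as one vectorized batch (a single time loop over all
windows), but every window consumes its own ``default_rng(base_seed + index)``
stream, so a window simulated alone is bit-identical to the same window
inside a protocol batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .constants import beta as _beta
from .landscapes import DEFAULT_SUPPORT, DiffusivityModel, EnergyLandscape

__all__ = [
    "UmbrellaProtocol",
    "WindowTrace",
    "default_protocol",
    "half_protocol",
    "simulate_window",
    "simulate_protocol",
    "simulate_ensemble",
]

#: dt * D * beta * k must stay below this for the biased OU update to be
#: comfortably stable and low-bias.
STABILITY_LIMIT = 0.1


def _default_centers() -> Tuple[float, ...]:
    # 22 windows spaced 0.2 nm apart spanning the bilayer: -2.1 .. +2.1 nm.
    return tuple(np.round(np.linspace(-2.1, 2.1, 22), 10))


@dataclass(frozen=True)
class UmbrellaProtocol:
    """Umbrella-sampling window layout and integrator settings.

    Defaults mirror the sampling protocol the pipeline is built for:
    22 windows spaced 0.2 nm apart, harmonic force constant 100 kJ/mol/nm^2,
    310 K.  ``n_steps`` = 2e5 at dt = 0.01 ps with the first 20% discarded is
    the desk-scale stand-in for the production-length windows.
    """

    window_centers: Tuple[float, ...] = field(default_factory=_default_centers)
    force_constant: float = 100.0     # kJ/mol/nm^2
    temperature: float = 310.0        # K
    dt: float = 0.01                  # ps
    n_steps: int = 200_000
    discard_fraction: float = 0.2
    save_stride: int = 10
    base_seed: int = 2022

    def __post_init__(self) -> None:
        c = np.asarray(self.window_centers, dtype=float)
        if c.size == 0:
            raise ValueError("protocol needs at least one window center")
        if np.any(np.diff(c) <= 0):
            raise ValueError("window centers must be sorted strictly ascending")
        if not 0.0 <= self.discard_fraction < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.force_constant <= 0 or self.temperature <= 0:
            raise ValueError("force constant and temperature must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")

    @property
    def discard_steps(self) -> int:
        return int(self.n_steps * self.discard_fraction)

    @property
    def n_saved(self) -> int:
        n_keep = self.n_steps - self.discard_steps
        return -(-n_keep // self.save_stride)  # ceil division


def default_protocol(**overrides) -> UmbrellaProtocol:
    """The 22-window full-membrane default protocol."""
    return UmbrellaProtocol(**overrides)


def half_protocol(side: str = "outer", **overrides) -> UmbrellaProtocol:
    """Single-leaflet protocol: 12 windows, bulk water to membrane core.

    ``side="outer"`` spans -2.2..0.0 nm, ``"inner"`` 0.0..+2.2 nm, at the
    same 0.2 nm spacing as the full protocol.
    """
    if side == "outer":
        centers = tuple(np.round(np.linspace(-2.2, 0.0, 12), 10))
    elif side == "inner":
        centers = tuple(np.round(np.linspace(0.0, 2.2, 12), 10))
    else:
        raise ValueError(f"side must be 'outer' or 'inner', got {side!r}")
    return UmbrellaProtocol(window_centers=centers, **overrides)


@dataclass(frozen=True)
class WindowTrace:
    """One umbrella window's saved (t, z) series with its bias parameters."""

    center: float            # nm
    force_constant: float    # kJ/mol/nm^2
    times: np.ndarray        # ps, strictly increasing, uniform stride
    positions: np.ndarray    # nm
    seed: int
    temperature: float = 310.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        z = np.asarray(self.positions, dtype=float)
        if t.shape != z.shape or t.ndim != 1:
            raise ValueError("times and positions must be matching 1-D arrays")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must have a uniform stride")
        if not np.all(np.isfinite(z)):
            raise ValueError("positions contain non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", z)

    @property
    def stride(self) -> float:
        """Sampling interval in ps."""
        if self.times.size < 2:
            raise ValueError("trace too short to define a stride")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)

    def time_slice(self, fraction: float) -> "WindowTrace":
        """First ``fraction`` of the trace (for convergence checks)."""
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        n = max(1, int(round(fraction * len(self))))
        return replace(self, times=self.times[:n], positions=self.positions[:n])


def _check_stability(landscape: EnergyLandscape, diff: DiffusivityModel,
                     protocol: UmbrellaProtocol) -> None:
    zs = np.linspace(landscape.support[0], landscape.support[1], 201)
    d_max = float(np.max(diff.value(zs)))
    guard = protocol.dt * d_max * _beta(protocol.temperature) * protocol.force_constant
    if guard >= STABILITY_LIMIT:
        raise ValueError(
            f"integrator stability guard violated: dt*D*beta*k = {guard:.3g} "
            f">= {STABILITY_LIMIT} — reduce dt or D")


def _reflect(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    z = np.where(z < lo, 2.0 * lo - z, z)
    z = np.where(z > hi, 2.0 * hi - z, z)
    # a pathological step could overshoot both reflections; clip as backstop
    return np.clip(z, lo, hi)


def _simulate_batch(landscape: EnergyLandscape, diff: DiffusivityModel,
                    centers: np.ndarray, protocol: UmbrellaProtocol,
                    seeds: Sequence[int], z0: np.ndarray,
                    include_spurious_drift: bool = True,
                    apply_bias: bool = True) -> np.ndarray:
    """Integrate all columns in lockstep; returns saved positions (n_saved, W)."""
    lo, hi = landscape.support
    b = _beta(protocol.temperature)
    k = protocol.force_constant if apply_bias else 0.0
    dt = protocol.dt
    n_steps, stride, discard = protocol.n_steps, protocol.save_stride, protocol.discard_steps
    W = centers.size
    rngs = [np.random.default_rng(int(s)) for s in seeds]

    z = np.array(z0, dtype=float, copy=True)
    out = np.empty((protocol.n_saved, W), dtype=float)
    const_d = diff.is_constant
    if const_d:
        d_val = float(diff.value(0.5 * (lo + hi)))
        noise_amp = np.sqrt(2.0 * d_val * dt)

    # per-window noise streams, drawn in chunks to bound memory
    chunk = max(1, min(50_000, 16_000_000 // W))
    i_out = 0
    for start in range(0, n_steps, chunk):
        n_chunk = min(chunk, n_steps - start)
        noise = np.empty((n_chunk, W), dtype=float)
        for j, rng in enumerate(rngs):
            noise[:, j] = rng.standard_normal(n_chunk)
        for i in range(n_chunk):
            step = start + i
            force = -landscape.gradient(z)
            if apply_bias:
                force = force - k * (z - centers)
            if const_d:
                drift = b * d_val * force
                z = z + drift * dt + noise_amp * noise[i]
            else:
                d = diff.value(z)
                drift = b * d * force
                if include_spurious_drift:
                    drift = drift + diff.gradient(z)
                z = z + drift * dt + np.sqrt(2.0 * d * dt) * noise[i]
            z = _reflect(z, lo, hi)
            if step >= discard and (step - discard) % stride == 0:
                out[i_out] = z
                i_out += 1
    assert i_out == protocol.n_saved
    return out


def _saved_times(protocol: UmbrellaProtocol) -> np.ndarray:
    idx = protocol.discard_steps + protocol.save_stride * np.arange(protocol.n_saved)
    return idx * protocol.dt


def simulate_window(landscape: EnergyLandscape, diff: DiffusivityModel,
                    center: float, protocol: UmbrellaProtocol,
                    window_index: int = 0, *,
                    include_spurious_drift: bool = True) -> WindowTrace:
    """Simulate one harmonically biased window started at its center.

    The window's RNG stream is seeded ``protocol.base_seed + window_index``.
    Raises if the center lies outside the landscape support or the stability
    guard dt*D*beta*k < 0.1 fails.
    """
    lo, hi = landscape.support
    if not lo <= center <= hi:
        raise ValueError(f"window center {center} outside support [{lo}, {hi}]")
    diff.validate_positive()
    _check_stability(landscape, diff, protocol)
    seed = protocol.base_seed + window_index
    saved = _simulate_batch(landscape, diff, np.array([center], dtype=float),
                            protocol, [seed], np.array([center], dtype=float),
                            include_spurious_drift=include_spurious_drift)
    return WindowTrace(center=float(center), force_constant=protocol.force_constant,
                       times=_saved_times(protocol), positions=saved[:, 0],
                       seed=seed, temperature=protocol.temperature)


def simulate_protocol(landscape: EnergyLandscape, diff: DiffusivityModel,
                      protocol: UmbrellaProtocol, *,
                      include_spurious_drift: bool = True) -> List[WindowTrace]:
    """Simulate every window of the protocol.

    Windows are advanced in one vectorized batch but with independent
    per-window RNG streams (seed = base_seed + index), so results are
    bit-identical to calling :func:`simulate_window` per window.
    """
    centers = np.asarray(protocol.window_centers, dtype=float)
    lo, hi = landscape.support
    for i, c in enumerate(centers):
        if not lo <= c <= hi:
            raise ValueError(f"window {i} center {c} outside support [{lo}, {hi}]")
    diff.validate_positive()
    _check_stability(landscape, diff, protocol)
    seeds = [protocol.base_seed + i for i in range(centers.size)]
    saved = _simulate_batch(landscape, diff, centers, protocol, seeds,
                            centers.copy(), include_spurious_drift=include_spurious_drift)
    times = _saved_times(protocol)
    return [WindowTrace(center=float(c), force_constant=protocol.force_constant,
                        times=times, positions=saved[:, j], seed=seeds[j],
                        temperature=protocol.temperature)
            for j, c in enumerate(centers)]


def simulate_ensemble(landscape: EnergyLandscape, diff: DiffusivityModel,
                      center: float, protocol: UmbrellaProtocol,
                      n_replicas: int, *, include_spurious_drift: bool = True,
                      apply_bias: bool = True) -> np.ndarray:
    """Independent replicas of one window; returns samples (n_saved, n_replicas).

    Used for stationary-distribution checks: with ``save_stride`` a few
    correlation times, the pooled samples are effectively independent draws
    from the biased Boltzmann density.  Replica j uses seed base_seed + j.
    """
    lo, hi = landscape.support
    if not lo <= center <= hi:
        raise ValueError(f"center {center} outside support [{lo}, {hi}]")
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    diff.validate_positive()
    if apply_bias:
        _check_stability(landscape, diff, protocol)
    seeds = [protocol.base_seed + j for j in range(n_replicas)]
    centers = np.full(n_replicas, float(center))
    return _simulate_batch(landscape, diff, centers, protocol, seeds,
                           centers.copy(), include_spurious_drift=include_spurious_drift,
                           apply_bias=apply_bias)
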