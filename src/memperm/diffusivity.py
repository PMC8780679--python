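"""Position-dependent diffusion coefficients from restrained trajectories.

Each harmonically restrained window yields a local diffusion coefficient via
the variance/autocorrelation estimator (Hummer, 2005)::

    D(z) = var(z)^2 / integral_0^inf C_zz(t) dt

where C_zz is the autocovariance of the window's position about its mean.
For an overdamped harmonic well (an Ornstein-Uhlenbeck process) this is an
identity: var = 1/(beta k), C_zz(t) = var exp(-t/tau) with tau = 1/(beta k D),
so var^2 / (var tau) = D.

The infinite upper limit is truncated in practice; the default rule stops at
the ACF's first non-positive value, the standard bias/variance compromise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .langevin import WindowTrace

__all__ = [
    "AcfSeries",
    "DiffusivityProfile",
    "autocorrelation",
    "autocorrelation_direct",
    "integrate_acf",
    "window_diffusivity",
    "diffusivity_profile",
    "WindowDiffusivity",
]

DEFAULT_MAX_LAG = 50.0   # ps; much longer than tau ~ 1/(beta k D) ~ 0.6 ps
                         # at the default protocol settings


@dataclass(frozen=True)
class AcfSeries:
    """Autocovariance of z about its mean, biased normalization (by n)."""

    lags: np.ndarray      # ps, starting at 0
    values: np.ndarray    # nm^2; values[0] == var(z)
    n_origin: int         # series length the ACF was computed from

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if lags.shape != vals.shape or lags.ndim != 1:
            raise ValueError("lags and values must be matching 1-D arrays")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", vals)

    @property
    def variance(self) -> float:
        return float(self.values[0])


@dataclass(frozen=True)
class WindowDiffusivity:
    """Per-window estimator record."""

    z_mean: float          # nm, where the fluctuations were measured
    variance: float        # nm^2
    acf_integral: float    # nm^2 * ps
    D: float               # nm^2/ps
    truncation_lag: float  # ps
    center: float          # nm, bias center (diagnostic)


@dataclass(frozen=True)
class DiffusivityProfile:
    """D(z) on a PMF grid, assembled from per-window estimates."""

    z_grid: np.ndarray
    D: np.ndarray
    windows: Tuple[WindowDiffusivity, ...]
    side: str = "full"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_grid, dtype=float)
        d = np.asarray(self.D, dtype=float)
        if z.shape != d.shape or z.ndim != 1:
            raise ValueError("z_grid and D must be matching 1-D arrays")
        if np.any(d <= 0):
            raise ValueError("diffusivity profile must be strictly positive")
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "D", d)


def autocorrelation(trace: WindowTrace, max_lag: float = DEFAULT_MAX_LAG) -> AcfSeries:
    """FFT-based autocovariance C(tau) of the window positions.

    Biased normalization by n at every lag (not n - tau), so C(0) equals the
    sample variance exactly.  ``max_lag`` (ps) may not exceed half the trace
    duration, and the trace must be at least 10 times max_lag long.
    """
    n = len(trace)
    if n < 2:
        raise ValueError("trace too short for an autocorrelation")
    stride = trace.stride
    m = int(np.floor(max_lag / stride + 1e-9))
    if m > n // 2:
        raise ValueError(f"max_lag {max_lag} ps exceeds half the trace length "
                         f"({n * stride / 2:.1f} ps)")
    if n < 10 * max(m, 1):
        raise ValueError(f"trace length {n} below 10 x (max_lag/stride) = {10 * m}")
    x = trace.positions - trace.positions.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: m + 1] / n
    return AcfSeries(lags=stride * np.arange(m + 1), values=acov, n_origin=n)


def autocorrelation_direct(positions: np.ndarray, stride: float, m: int) -> AcfSeries:
    """Double-loop reference ACF (biased, by n); oracle for the FFT path."""
    x = np.asarray(positions, dtype=float)
    x = x - x.mean()
    n = x.size
    vals = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(m + 1)])
    return AcfSeries(lags=stride * np.arange(m + 1), values=vals, n_origin=n)


def integrate_acf(acf: AcfSeries, rule: str = "first_zero") -> Tuple[float, float]:
    """Trapezoidal integral of the ACF from lag 0 (nm^2 * ps).

    rule="first_zero" (default) integrates through the first non-positive
    ACF value; rule="full" uses every tabulated lag.  Returns
    ``(integral, truncation_lag)``.
    """
    if acf.values[0] <= 0:
        raise ValueError("ACF must be positive at lag 0")
    if rule == "full":
        stop = acf.values.size - 1
    elif rule == "first_zero":
        nonpos = np.flatnonzero(acf.values[1:] <= 0.0)
        stop = int(nonpos[0]) + 1 if nonpos.size else acf.values.size - 1
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    integral = float(np.trapezoid(acf.values[: stop + 1], acf.lags[: stop + 1]))
    return integral, float(acf.lags[stop])


def window_diffusivity(trace: WindowTrace, max_lag: float = DEFAULT_MAX_LAG,
                       rule: str = "first_zero") -> WindowDiffusivity:
    """Local D from one restrained window: var(z)^2 / integral C_zz dt.

    The estimate is anchored at the window's sample-mean z — with a tilted
    local PMF that is where the fluctuations were actually measured — not at
    the bias center.
    """
    acf = autocorrelation(trace, max_lag=max_lag)
    integral, trunc = integrate_acf(acf, rule=rule)
    if integral <= 0:
        raise ValueError(f"non-positive ACF integral ({integral:.3g}) in window at "
                         f"center {trace.center}: inadequate sampling")
    var = acf.variance
    return WindowDiffusivity(z_mean=float(trace.positions.mean()), variance=var,
                             acf_integral=integral, D=var * var / integral,
                             truncation_lag=trunc, center=trace.center)


def diffusivity_profile(traces: Sequence[WindowTrace], pmf_grid: np.ndarray,
                        side: str = "full", max_lag: float = DEFAULT_MAX_LAG,
                        rule: str = "first_zero") -> DiffusivityProfile:
    """Assemble D(z) on the PMF grid from per-window estimates.

    Per-window values are linearly interpolated between their sample-mean
    positions, with constant extrapolation beyond the outermost means.  For
    ``side="cancer"`` (one sampled leaflet duplicated) the estimates are
    mirrored about z = 0 before interpolation, matching the PMF convention.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 windows for a diffusivity profile")
    records = []
    for i, tr in enumerate(traces):
        try:
            records.append(window_diffusivity(tr, max_lag=max_lag, rule=rule))
        except ValueError as exc:
            raise ValueError(f"window {i} (center {tr.center} nm): {exc}") from exc
    zs = np.array([r.z_mean for r in records])
    ds = np.array([r.D for r in records])
    pmf_grid = np.asarray(pmf_grid, dtype=float)
    if side == "cancer":
        # one sampled leaflet duplicated: D is a function of |z|, which makes
        # the mirrored profile exactly symmetric on symmetric grids
        zs, query = np.abs(zs), np.abs(pmf_grid)
    else:
        query = pmf_grid
    order = np.argsort(zs)
    zs, ds = zs[order], ds[order]
    d_interp = np.interp(query, zs, ds)      # np.interp clamps: constant extrapolation
    return DiffusivityProfile(z_grid=pmf_grid, D=d_interp, windows=tuple(records),
                              side=side, meta={"max_lag_ps": max_lag, "rule": rule})
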