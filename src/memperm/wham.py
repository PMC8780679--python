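"""Weighted Histogram Analysis Method and PMF post-processing.

Turns the biased per-window position histograms into one unbiased potential
of mean force dG(z), then applies the reporting conventions used for
membrane permeation profiles: zero-referencing to bulk water, a 0.05 nm
(0.5 angstrom) moving-average smoothing, duplication of one leaflet for a
symmetric (PS-exposing, "cancer") membrane, and joining of two independently
sampled leaflets for an asymmetric ("normal") membrane.

The self-consistent WHAM equations iterated by :func:`solve_wham` are::

    rho(z_b) = sum_i n_i(z_b) / sum_i N_i f_i exp(-beta w_i(z_b))
    1 / f_i  = sum_b rho(z_b) exp(-beta w_i(z_b)) dz

with w_i(z) = k/2 (z - c_i)^2, stopping when the largest change of the
window free energies -RT ln f_i between sweeps falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .constants import beta as _beta, rt as _rt
from .langevin import WindowTrace

__all__ = [
    "HistogramSet",
    "PmfProfile",
    "WhamConvergenceError",
    "build_histograms",
    "solve_wham",
    "block_stderr",
    "reference_to_bulk",
    "smooth_pmf",
    "symmetrize_cancer",
    "join_normal_leaflets",
    "check_convergence",
    "ConvergenceReport",
]

#: Default WHAM numerical settings (standard practice; the method itself does
#: not prescribe them).
DEFAULT_BIN_WIDTH = 0.02     # nm
DEFAULT_TOL = 1e-7           # kJ/mol on the window free energies
DEFAULT_MAX_ITER = 100_000
#: Downstream stages refuse histograms losing more than this fraction of
#: samples outside the binning range.
MAX_OVERFLOW_FRACTION = 0.01


class WhamConvergenceError(RuntimeError):
    """WHAM iteration failed to converge; carries diagnostics."""

    def __init__(self, message: str, iterations: int, last_delta: float):
        super().__init__(message)
        self.iterations = iterations
        self.last_delta = last_delta


@dataclass(frozen=True)
class HistogramSet:
    """Shared-grid histograms of every umbrella window (rows not pooled)."""

    bin_edges: np.ndarray        # (B+1,) nm, uniform width
    counts: np.ndarray           # (W, B) integer counts
    n_samples: np.ndarray        # (W,) totals inside the range
    centers: np.ndarray          # (W,) bias centers, nm
    force_constants: np.ndarray  # (W,) kJ/mol/nm^2
    n_overflow: int              # samples outside [z_lo, z_hi) over all windows
    temperature: float = 310.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin edges must be strictly increasing and uniform")
        if self.counts.shape != (self.centers.size, edges.size - 1):
            raise ValueError("counts shape inconsistent with windows/edges")
        if not np.array_equal(self.counts.sum(axis=1), self.n_samples):
            raise ValueError("per-window counts do not sum to n_samples")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def overflow_fraction(self) -> float:
        total = int(self.n_samples.sum()) + self.n_overflow
        return self.n_overflow / total if total else 0.0


@dataclass(frozen=True)
class PmfProfile:
    """Gridded free-energy profile dG(z) on histogram-bin midpoints.

    ``mask`` flags bins with no information (no counts in any window); their
    dG is NaN and they are excluded from referencing, smoothing and
    integration.
    """

    z_grid: np.ndarray           # nm, bin midpoints, ascending
    dG: np.ndarray               # kJ/mol
    stderr: np.ndarray | None = None   # kJ/mol, from block analysis
    reference: str = "raw"       # "raw" | "bulk-zeroed"
    side: str = "full"           # "outer" | "inner" | "full"
    smoothed: bool = False
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_grid, dtype=float)
        g = np.asarray(self.dG, dtype=float)
        if z.shape != g.shape or z.ndim != 1:
            raise ValueError("z_grid and dG must be matching 1-D arrays")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z_grid must be strictly ascending")
        m = (np.zeros(z.size, dtype=bool) if self.mask is None
             else np.asarray(self.mask, dtype=bool))
        if m.shape != z.shape:
            raise ValueError("mask shape mismatch")
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "dG", g)
        object.__setattr__(self, "mask", m)
        if self.stderr is not None:
            e = np.asarray(self.stderr, dtype=float)
            if e.shape != z.shape:
                raise ValueError("stderr shape mismatch")
            object.__setattr__(self, "stderr", e)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def __len__(self) -> int:
        return int(self.z_grid.size)


def build_histograms(traces: Sequence[WindowTrace], bin_width: float = DEFAULT_BIN_WIDTH,
                     z_range: Tuple[float, float] = (-2.2, 2.2)) -> HistogramSet:
    """Bin every window's positions on one shared uniform grid.

    Bins are half-open [edge_i, edge_{i+1}); samples outside ``z_range`` are
    counted as overflow, reported on the result and rejected downstream if
    they exceed 1% of all samples.
    """
    if not traces:
        raise ValueError("no traces supplied")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    z_lo, z_hi = z_range
    if not z_lo < z_hi:
        raise ValueError("zero-width histogram range")
    n_bins = int(np.ceil((z_hi - z_lo) / bin_width - 1e-9))
    edges = z_lo + bin_width * np.arange(n_bins + 1)

    counts = np.zeros((len(traces), n_bins), dtype=np.int64)
    n_samples = np.zeros(len(traces), dtype=np.int64)
    n_overflow = 0
    for w, tr in enumerate(traces):
        idx = np.floor((tr.positions - z_lo) / bin_width).astype(np.int64)
        inside = (idx >= 0) & (idx < n_bins)
        n_overflow += int((~inside).sum())
        counts[w] = np.bincount(idx[inside], minlength=n_bins)
        n_samples[w] = int(inside.sum())
    temps = {tr.temperature for tr in traces}
    if len(temps) > 1:
        raise ValueError(f"traces at mixed temperatures: {sorted(temps)}")
    return HistogramSet(bin_edges=edges, counts=counts, n_samples=n_samples,
                        centers=np.array([tr.center for tr in traces], dtype=float),
                        force_constants=np.array([tr.force_constant for tr in traces],
                                                 dtype=float),
                        n_overflow=n_overflow, temperature=temps.pop())


def solve_wham(hist: HistogramSet, temperature: float | None = None,
               tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
               side: str = "full", f_init: np.ndarray | None = None) -> PmfProfile:
    """Iterate the WHAM equations to the unbiased PMF (raw reference).

    Bins with zero total count across all windows are masked.  Raises
    :class:`WhamConvergenceError` if the window free energies have not
    stabilised to ``tol`` (kJ/mol) within ``max_iter`` sweeps.  ``f_init``
    seeds the window normalization constants (default all ones); the
    converged profile is gauge invariant to this choice.
    """
    if temperature is None:
        temperature = hist.temperature
    if hist.overflow_fraction >= MAX_OVERFLOW_FRACTION:
        raise ValueError(f"histogram overflow fraction {hist.overflow_fraction:.2%} "
                         f"exceeds {MAX_OVERFLOW_FRACTION:.0%}; widen the range")
    b = _beta(temperature)
    rt_val = _rt(temperature)
    mids = hist.midpoints
    dz = hist.bin_width
    total = hist.counts.sum(axis=0).astype(float)      # (B,)
    mask = total == 0.0
    valid = ~mask
    if not valid.any():
        raise ValueError("all histogram bins are empty")

    # bias Boltzmann factors, (W, B) on valid bins only
    w_bias = 0.5 * hist.force_constants[:, None] * (mids[None, :] - hist.centers[:, None]) ** 2
    A = np.exp(-b * w_bias[:, valid])
    N = hist.n_samples.astype(float)                   # (W,)
    num = total[valid]                                 # sum_i n_i(z_b)

    f = (np.ones(N.size, dtype=float) if f_init is None
         else np.asarray(f_init, dtype=float).copy())
    if f.shape != N.shape or np.any(f <= 0):
        raise ValueError("f_init must be positive, one value per window")
    g_old = np.zeros(N.size, dtype=float)
    converged = False
    iterations = 0
    delta = np.inf
    for iterations in range(1, max_iter + 1):
        denom = (N * f) @ A                            # (B_valid,)
        rho = num / denom
        f_new = 1.0 / ((A @ rho) * dz)
        f_new /= f_new[0]                              # gauge fix
        g_new = -rt_val * np.log(f_new)
        delta = float(np.max(np.abs(g_new - g_old))) if iterations > 1 else np.inf
        f = f_new
        g_old = g_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (last delta "
            f"{delta:.3g} kJ/mol > tol {tol:g})", iterations, delta)

    denom = (N * f) @ A
    rho = num / denom
    dG = np.full(mids.size, np.nan)
    dG[valid] = -rt_val * np.log(rho)
    dG[valid] -= np.nanmin(dG[valid])
    return PmfProfile(z_grid=mids, dG=dG, reference="raw", side=side, mask=mask,
                      meta={"temperature_K": temperature, "bin_width_nm": dz,
                            "tol_kj_mol": tol, "iterations": iterations,
                            "overflow_fraction": hist.overflow_fraction})


def block_stderr(traces: Sequence[WindowTrace], n_blocks: int = 5,
                 bin_width: float = DEFAULT_BIN_WIDTH,
                 z_range: Tuple[float, float] = (-2.2, 2.2),
                 temperature: float | None = None,
                 tol: float = 1e-5, max_iter: int = DEFAULT_MAX_ITER) -> np.ndarray:
    """Statistical error of the PMF by block averaging.

    Each trace is split into ``n_blocks`` contiguous time blocks; WHAM is
    solved per block and the standard error over blocks (aligned per bin,
    after removing each block's mean over commonly valid bins) is returned
    on the full grid (NaN where fewer than two blocks have data).
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    n = min(len(tr) for tr in traces)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    profiles = []
    for b0, b1 in zip(edges[:-1], edges[1:]):
        blk = [replace(tr, times=tr.times[b0:b1], positions=tr.positions[b0:b1])
               for tr in traces]
        hist = build_histograms(blk, bin_width=bin_width, z_range=z_range)
        profiles.append(solve_wham(hist, temperature=temperature, tol=tol,
                                   max_iter=max_iter))
    grids = np.array([p.dG for p in profiles])         # (K, B), NaN where masked
    common = np.all(np.isfinite(grids), axis=0)
    if common.any():
        grids = grids - np.nanmean(grids[:, common], axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        counts = np.sum(np.isfinite(grids), axis=0)
        std = np.nanstd(grids, axis=0, ddof=1)
    err = np.where(counts >= 2, std / np.sqrt(np.maximum(counts, 1)), np.nan)
    return err


def _regions(bulk_region) -> List[Tuple[float, float]]:
    if isinstance(bulk_region, (tuple, list)) and len(bulk_region) == 2 \
            and np.isscalar(bulk_region[0]):
        return [tuple(map(float, bulk_region))]
    return [tuple(map(float, r)) for r in bulk_region]


def reference_to_bulk(pmf: PmfProfile, bulk_region) -> PmfProfile:
    """Shift the profile so its mean over the bulk-water region is zero.

    ``bulk_region`` is one (z_a, z_b) interval or a list of intervals (for a
    full profile with bulk on both sides).  Idempotent.
    """
    sel = np.zeros(len(pmf), dtype=bool)
    for a, bz in _regions(bulk_region):
        sel |= (pmf.z_grid >= a) & (pmf.z_grid <= bz)
    sel &= pmf.valid
    if not sel.any():
        raise ValueError(f"bulk region {bulk_region} has no valid overlap with the grid")
    shift = float(np.mean(pmf.dG[sel]))
    meta = dict(pmf.meta, bulk_region=_regions(bulk_region))
    return replace(pmf, dG=pmf.dG - shift, reference="bulk-zeroed", meta=meta)


def smooth_pmf(pmf: PmfProfile, span: float = 0.05) -> PmfProfile:
    """Centered moving average over all grid points within +-span/2.

    The averaging window is truncated (not padded) at the profile ends and
    skips masked bins.  Standard errors, if present, are propagated as the
    error of the window mean assuming independent bins.
    """
    dz = float(np.median(np.diff(pmf.z_grid)))
    if span < dz - 1e-12:
        raise ValueError(f"smoothing span {span} nm is below the bin width {dz} nm")
    half = span / 2.0
    n = len(pmf)
    out = np.full(n, np.nan)
    err = np.full(n, np.nan) if pmf.stderr is not None else None
    for i in range(n):
        if pmf.mask[i]:
            continue
        sel = (np.abs(pmf.z_grid - pmf.z_grid[i]) <= half + 1e-12) & pmf.valid
        out[i] = np.mean(pmf.dG[sel])
        if err is not None:
            e = pmf.stderr[sel]
            good = np.isfinite(e)
            if good.any():
                err[i] = np.sqrt(np.sum(e[good] ** 2)) / good.sum()
    meta = dict(pmf.meta, smoothing_span_nm=span)
    return replace(pmf, dG=out, stderr=err, smoothed=True, meta=meta)


def symmetrize_cancer(half: PmfProfile, atol: float = 1e-9) -> PmfProfile:
    """Duplicate an outer-leaflet (z <= 0) profile onto the other leaflet.

    For a membrane with the same lipid composition in both leaflets only one
    leaflet is sampled; the full profile is dG(+z) := dG(-z), exactly mirror
    symmetric.  Accepts a half profile whose grid reaches the core (a point
    within one bin of z = 0).
    """
    z, g = half.z_grid, half.dG
    keep = z <= atol
    if not keep.any():
        raise ValueError("half profile contains no z <= 0 points")
    z_half, g_half = z[keep], g[keep]
    m_half = half.mask[keep]
    e_half = half.stderr[keep] if half.stderr is not None else None
    dz = float(np.median(np.diff(z)))
    if z_half[-1] < -dz - 1e-9:
        raise ValueError(f"half profile stops at z = {z_half[-1]:.3f} nm, "
                         "short of the membrane core")
    has_zero = abs(z_half[-1]) <= atol
    sl = slice(-2, None, -1) if has_zero else slice(None, None, -1)
    z_full = np.concatenate([z_half, -z_half[sl]])
    g_full = np.concatenate([g_half, g_half[sl]])
    m_full = np.concatenate([m_half, m_half[sl]])
    e_full = (np.concatenate([e_half, e_half[sl]]) if e_half is not None else None)
    meta = dict(half.meta, assembly="leaflet-duplicated")
    return PmfProfile(z_grid=z_full, dG=g_full, stderr=e_full,
                      reference=half.reference, side="full",
                      smoothed=half.smoothed, mask=m_full, meta=meta)


def join_normal_leaflets(outer: PmfProfile, inner: PmfProfile,
                         atol: float = 1e-9) -> PmfProfile:
    """Concatenate independently sampled leaflet profiles at the core.

    Both halves must be bulk-referenced on their own side.  The inner
    (z >= 0) half is additively shifted so its value at the grid point
    nearest z = 0 equals the outer half's; the shift magnitude is reported
    as ``meta["core_mismatch_kj_mol"]`` — a diagnostic of how consistently
    the two leaflets place the core free energy.
    """
    for name, p in (("outer", outer), ("inner", inner)):
        if p.reference != "bulk-zeroed":
            raise ValueError(f"{name} half must be bulk-referenced before joining")
    keep_o = outer.z_grid <= atol
    keep_i = inner.z_grid >= -atol
    if not keep_o.any() or not keep_i.any():
        raise ValueError("leaflet halves do not cover their side of the core")
    zo, go, mo = outer.z_grid[keep_o], outer.dG[keep_o], outer.mask[keep_o]
    zi, gi, mi = inner.z_grid[keep_i], inner.dG[keep_i], inner.mask[keep_i]
    eo = outer.stderr[keep_o] if outer.stderr is not None else None
    ei = inner.stderr[keep_i] if inner.stderr is not None else None
    dz = float(np.median(np.diff(outer.z_grid)))
    if zo[-1] < -dz - 1e-9 or zi[0] > dz + 1e-9:
        raise ValueError("a leaflet half does not reach z ~ 0")
    io = np.flatnonzero(~mo)
    ii = np.flatnonzero(~mi)
    if io.size == 0 or ii.size == 0:
        raise ValueError("no valid bins near the core")
    shift = go[io[-1]] - gi[ii[0]]
    gi = gi + shift
    # avoid duplicated z=0 point
    if abs(zi[0] - zo[-1]) <= atol:
        zi, gi, mi = zi[1:], gi[1:], mi[1:]
        ei = ei[1:] if ei is not None else None
    meta = dict(outer.meta, assembly="leaflets-joined",
                core_mismatch_kj_mol=float(abs(shift)))
    return PmfProfile(z_grid=np.concatenate([zo, zi]), dG=np.concatenate([go, gi]),
                      stderr=(np.concatenate([eo, ei]) if eo is not None and ei is not None
                              else None),
                      reference="bulk-zeroed", side="full",
                      smoothed=outer.smoothed and inner.smoothed,
                      mask=np.concatenate([mo, mi]), meta=meta)


@dataclass(frozen=True)
class ConvergenceReport:
    """PMF stability across cumulative slices of the sampling."""

    fractions: Tuple[float, ...]
    max_deltas: Tuple[float, ...]   # kJ/mol between successive slices
    threshold: float
    converged: bool


def check_convergence(traces: Sequence[WindowTrace], n_intervals: int = 3,
                      threshold: float = 1.0,
                      bin_width: float = DEFAULT_BIN_WIDTH,
                      z_range: Tuple[float, float] = (-2.2, 2.2),
                      bulk_region=None, temperature: float | None = None,
                      tol: float = DEFAULT_TOL,
                      max_iter: int = DEFAULT_MAX_ITER,
                      min_counts: int = 25) -> ConvergenceReport:
    """Re-solve WHAM on cumulative time slices and compare successive PMFs.

    Slices are the first i/n_intervals of every trace (i = 1..n).  The
    profile is declared converged when the final successive max |delta dG|
    over commonly well-sampled bins (>= ``min_counts`` total counts in every
    slice, so the comparison measures drift rather than shot noise of barely
    visited bins) falls below ``threshold`` (default 1 kJ/mol).
    """
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals to compare")
    fractions = tuple((i + 1) / n_intervals for i in range(n_intervals))
    profiles, well_sampled = [], []
    for frac in fractions:
        sliced = [tr.time_slice(frac) for tr in traces]
        hist = build_histograms(sliced, bin_width=bin_width, z_range=z_range)
        if hist.n_samples.min() == 0:
            raise ValueError(f"slice {frac:.0%} leaves a window empty")
        pmf = solve_wham(hist, temperature=temperature, tol=tol, max_iter=max_iter)
        if bulk_region is not None:
            pmf = reference_to_bulk(pmf, bulk_region)
        profiles.append(pmf)
        well_sampled.append(hist.counts.sum(axis=0) >= min_counts)
    deltas = []
    for (a, wa), (b, wb) in zip(zip(profiles[:-1], well_sampled[:-1]),
                                zip(profiles[1:], well_sampled[1:])):
        common = a.valid & b.valid & wa & wb
        if not common.any():
            raise ValueError("successive slices share no valid bins")
        da = a.dG[common] - np.mean(a.dG[common])
        db = b.dG[common] - np.mean(b.dG[common])
        deltas.append(float(np.max(np.abs(da - db))))
    return ConvergenceReport(fractions=fractions, max_deltas=tuple(deltas),
                             threshold=threshold, converged=deltas[-1] < threshold)
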