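"""Model/Results interface for the umbrella-sampling permeation pipeline.

:class:`PermeationModel` is built from per-window reaction-coordinate
traces (plus the estimation settings) and its :meth:`~PermeationModel.fit`
runs the full chain

    histograms -> WHAM -> bulk referencing -> smoothing ->
    leaflet assembly -> D(z) -> R(z) -> R_eff -> P

returning a :class:`PermeationResults` that carries every intermediate
profile, the permeability coefficient with its provenance, diagnostics and
a ``summary()`` table.

Two membrane modes reflect how the leaflets were sampled:

- ``"cancer"``: the membrane is symmetric (PS exposed in both leaflets), so
  one leaflet's windows are estimated and the PMF is duplicated onto the
  other leaflet.
- ``"normal"``: the leaflets differ (PS only inside), each is sampled
  independently; the two bulk-referenced half profiles are joined at the
  core with the offset reported as a consistency diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np

from . import wham as _wham
from .diffusivity import DiffusivityProfile, diffusivity_profile
from .langevin import WindowTrace
from .permeability import (PermeabilityResult, ResistivityProfile,
                           effective_resistivity, permeability,
                           resistivity_profile)
from .wham import PmfProfile

__all__ = ["PermeationModel", "PermeationResults", "run_pipeline"]

#: Histogram range is padded this far (nm) past the core so the core-centred
#: window's fluctuations across z=0 are binned, not counted as overflow.
CORE_PAD = 0.6


@dataclass(frozen=True)
class PermeationResults:
    """Fitted permeation pipeline: profiles, permeability and diagnostics."""

    model: "PermeationModel"
    pmf: PmfProfile                      # full membrane, referenced (+smoothed)
    pmf_halves: tuple                    # referenced, unsmoothed half profiles
    diffusivity: DiffusivityProfile
    resistivity: ResistivityProfile
    permeability: PermeabilityResult
    wham_iterations: int
    core_mismatch: float | None = None   # kJ/mol, normal mode only

    @property
    def R_eff(self) -> float:
        return self.permeability.R_eff

    @property
    def P_cm_per_s(self) -> float:
        return self.permeability.P_cm_per_s

    @property
    def log10_P(self) -> float:
        return self.permeability.log10_P

    @property
    def dG_max(self) -> float:
        """Barrier height: maximum of the referenced PMF, kJ/mol."""
        return float(np.nanmax(self.pmf.dG))

    @property
    def dG_max_position(self) -> float:
        return float(self.pmf.z_grid[np.nanargmax(self.pmf.dG)])

    def check_convergence(self, n_intervals: int = 3, threshold: float = 1.0):
        """PMF stability over cumulative sampling slices (see wham module)."""
        m = self.model
        reports = []
        for traces, z_range, bulk in m._leaflet_jobs():
            reports.append(_wham.check_convergence(
                traces, n_intervals=n_intervals, threshold=threshold,
                bin_width=m.bin_width, z_range=z_range, bulk_region=bulk,
                temperature=m.temperature, tol=max(m.wham_tol, 1e-5)))
        return reports if len(reports) > 1 else reports[0]

    def summary(self) -> str:
        m = self.model
        p = self.permeability
        lines = [
            "          Membrane permeation (ISD model)",
            "=" * 55,
            f"membrane mode          {m.membrane_mode}",
            f"windows                {m.n_windows}",
            f"temperature            {m.temperature:.1f} K",
            f"WHAM bin width         {m.bin_width:.3f} nm "
            f"({self.wham_iterations} iterations)",
            f"smoothing span         {m.smoothing_span:.3f} nm",
            f"bulk region            |z| >= {m.bulk_edge:.2f} nm",
            f"integration bounds     [{p.z1:.2f}, {p.z2:.2f}] nm",
            "-" * 55,
            f"dG_max                 {self.dG_max:8.3f} kJ/mol "
            f"at z = {self.dG_max_position:+.2f} nm",
            f"D range                {self.diffusivity.D.min():.4f} .. "
            f"{self.diffusivity.D.max():.4f} nm^2/ps",
            f"R_eff                  {p.R_eff:12.4g} ps/nm",
            f"P                      {p.P_cm_per_s:12.4g} cm/s",
            f"log10 P                {p.log10_P:8.2f}",
        ]
        if self.core_mismatch is not None:
            lines.append(f"leaflet core mismatch  {self.core_mismatch:8.3f} kJ/mol")
        lines.append("=" * 55)
        return "\n".join(lines)


class PermeationModel:
    """ISD permeation estimator over umbrella-window traces.

    Parameters
    ----------
    traces_outer : sequence of WindowTrace
        Outer-leaflet windows (centers <= 0).  In cancer mode these are the
        only input.
    traces_inner : sequence of WindowTrace, optional
        Inner-leaflet windows (centers >= 0); required in normal mode.
    membrane_mode : {"cancer", "normal"}
    temperature : float, K (default: taken from the traces)
    bin_width, smoothing_span, bulk_edge, z1, z2 : floats, nm
        WHAM grid resolution, moving-average span, bulk-water edge used for
        zero referencing (|z| >= bulk_edge), and resistivity integration
        bounds (clamped to the estimated grid).
    max_lag, acf_rule
        Diffusivity estimator settings.
    use_smoothed : bool
        Feed the smoothed PMF into the resistivity (default); the raw
        referenced PMF is used when False.
    compute_errors : bool
        Attach block-averaged (5 blocks) PMF standard errors.
    """

    def __init__(self, traces_outer: Sequence[WindowTrace],
                 traces_inner: Sequence[WindowTrace] | None = None, *,
                 membrane_mode: str = "cancer", temperature: float | None = None,
                 bin_width: float = 0.02, smoothing_span: float = 0.05,
                 bulk_edge: float = 2.0, z1: float = -2.2, z2: float = 2.2,
                 max_lag: float = 50.0, acf_rule: str = "first_zero",
                 wham_tol: float = 1e-7, wham_max_iter: int = 100_000,
                 use_smoothed: bool = True, compute_errors: bool = False):
        if membrane_mode not in ("cancer", "normal"):
            raise ValueError(f"membrane_mode must be 'cancer' or 'normal', "
                             f"got {membrane_mode!r}")
        self.traces_outer = list(traces_outer)
        self.traces_inner = list(traces_inner) if traces_inner else []
        if not self.traces_outer:
            raise ValueError("no outer-leaflet traces supplied")
        if membrane_mode == "normal" and not self.traces_inner:
            raise ValueError("normal mode needs inner-leaflet traces")
        if membrane_mode == "cancer" and self.traces_inner:
            raise ValueError("cancer mode duplicates one leaflet; pass outer "
                             "traces only")
        if temperature is None:
            temperature = self.traces_outer[0].temperature
        self.membrane_mode = membrane_mode
        self.temperature = float(temperature)
        self.bin_width = bin_width
        self.smoothing_span = smoothing_span
        self.bulk_edge = bulk_edge
        self.z1, self.z2 = z1, z2
        self.max_lag = max_lag
        self.acf_rule = acf_rule
        self.wham_tol = wham_tol
        self.wham_max_iter = wham_max_iter
        self.use_smoothed = use_smoothed
        self.compute_errors = compute_errors

    @classmethod
    def from_manifest(cls, manifest, config) -> "PermeationModel":
        """Build from an :class:`~memperm.io.Manifest` and RunConfig."""
        traces = {side: [] for side in ("outer", "inner")}
        for row in manifest.rows:
            if row.side not in traces:
                raise ValueError(f"unknown side tag {row.side!r} in manifest")
            from .io import read_trace
            traces[row.side].append(read_trace(
                row.trace_path, center=row.center_nm,
                force_constant=row.force_constant, seed=row.seed,
                temperature=config.temperature_K))
        inner = traces["inner"] or None
        if config.membrane_mode == "cancer" and inner:
            raise ValueError("cancer-mode manifest must contain only outer windows")
        return cls(traces["outer"], inner, membrane_mode=config.membrane_mode,
                   temperature=config.temperature_K, bin_width=config.bin_width_nm,
                   smoothing_span=config.smoothing_span_nm,
                   bulk_edge=config.bulk_edge_nm, z1=config.z1_nm, z2=config.z2_nm,
                   max_lag=config.max_lag_ps, acf_rule=config.acf_rule)

    @property
    def n_windows(self) -> int:
        return len(self.traces_outer) + len(self.traces_inner)

    def _leaflet_jobs(self):
        """(traces, histogram range, bulk region) per independently solved leaflet."""
        jobs = [(self.traces_outer, (self.z1, CORE_PAD),
                 (self.z1, -self.bulk_edge))]
        if self.membrane_mode == "normal":
            jobs.append((self.traces_inner, (-CORE_PAD, self.z2),
                         (self.bulk_edge, self.z2)))
        return jobs

    def _solve_half(self, traces, z_range, bulk, side) -> PmfProfile:
        hist = _wham.build_histograms(traces, bin_width=self.bin_width,
                                      z_range=z_range)
        pmf = _wham.solve_wham(hist, temperature=self.temperature,
                               tol=self.wham_tol, max_iter=self.wham_max_iter,
                               side=side)
        if self.compute_errors:
            err = _wham.block_stderr(traces, bin_width=self.bin_width,
                                     z_range=z_range, temperature=self.temperature)
            pmf = PmfProfile(z_grid=pmf.z_grid, dG=pmf.dG, stderr=err,
                             reference=pmf.reference, side=pmf.side,
                             smoothed=pmf.smoothed, mask=pmf.mask, meta=pmf.meta)
        return _wham.reference_to_bulk(pmf, bulk)

    def fit(self) -> PermeationResults:
        """Run the estimation pipeline end to end."""
        jobs = self._leaflet_jobs()
        halves: List[PmfProfile] = []
        iterations = 0
        for (traces, z_range, bulk), side in zip(jobs, ("outer", "inner")):
            half = self._solve_half(traces, z_range, bulk, side)
            iterations += int(half.meta.get("iterations", 0))
            halves.append(half)

        core_mismatch = None
        if self.membrane_mode == "cancer":
            smooth_half = _wham.smooth_pmf(halves[0], span=self.smoothing_span)
            full = _wham.symmetrize_cancer(smooth_half if self.use_smoothed
                                           else halves[0])
        else:
            smoothed = [_wham.smooth_pmf(h, span=self.smoothing_span)
                        for h in halves]
            use = smoothed if self.use_smoothed else halves
            full = _wham.join_normal_leaflets(use[0], use[1])
            core_mismatch = full.meta.get("core_mismatch_kj_mol")

        all_traces = self.traces_outer + self.traces_inner
        side = "cancer" if self.membrane_mode == "cancer" else "normal"
        # the ACF needs >= 10 max_lag spans of data; cap for short traces
        stride = all_traces[0].stride
        max_lag = min(self.max_lag,
                      min(len(t) for t in all_traces) * stride / 10.0)
        diff = diffusivity_profile(all_traces, full.z_grid, side=side,
                                   max_lag=max_lag, rule=self.acf_rule)
        resist = resistivity_profile(full, diff, temperature=self.temperature)
        grid = full.z_grid
        z1 = max(self.z1, float(grid[0]))
        z2 = min(self.z2, float(grid[-1]))
        r_eff = effective_resistivity(resist, z1, z2)
        perm = permeability(r_eff, z1=z1, z2=z2, temperature=self.temperature,
                            meta={"membrane_mode": self.membrane_mode,
                                  "n_windows": self.n_windows,
                                  "pmf_smoothed": full.smoothed})
        return PermeationResults(model=self, pmf=full, pmf_halves=tuple(halves),
                                 diffusivity=diff, resistivity=resist,
                                 permeability=perm, wham_iterations=iterations,
                                 core_mismatch=core_mismatch)


def run_pipeline(manifest, config, out_dir=None) -> PermeationResults:
    """Fit the full pipeline from a manifest; optionally write all artifacts.

    ``manifest`` may be a path or a loaded :class:`~memperm.io.Manifest`.
    Artifacts (pmf.txt, diffusivity.txt, resistivity.txt, result.txt) carry
    the config hash so a run can be reproduced from its outputs.
    """
    from . import io as _io
    if not hasattr(manifest, "rows"):
        manifest = _io.read_manifest(manifest)
    model = PermeationModel.from_manifest(manifest, config)
    results = model.fit()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = {"config_hash": config.config_hash, "seed": config.seed}
        results.pmf.meta.update(prov)
        results.diffusivity.meta.update(prov)
        results.resistivity.meta.update(prov)
        results.permeability.meta.update(prov)
        _io.write_pmf(results.pmf, out / "pmf.txt")
        _io.write_diffusivity(results.diffusivity, out / "diffusivity.txt")
        _io.write_resistivity(results.resistivity, out / "resistivity.txt")
        _io.write_result(results.permeability, out / "result.txt")
    return results
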