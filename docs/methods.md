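# Methods

This note documents the models, estimators and numerical choices behind
`memperm`, and what the synthetic validation does and does not demonstrate.

## Scope and model

The package estimates the permeability coefficient P of a neutral solute
crossing a lipid bilayer from umbrella-sampling window time series, under
the inhomogeneous solubility-diffusion (ISD) model: permeation is treated as
1-D diffusion along the bilayer normal z with a position-dependent free
energy ΔG(z) and diffusion coefficient D(z), giving a local resistivity
R(z) = exp(βΔG(z))/D(z) and P = 1/∫R dz. ΔG is molar (kJ/mol), so
β = 1/(R_gas·T) with R_gas = 0.008314462618 kJ/mol/K; the default
temperature is 310 K. Internal units are nm, ps, kJ/mol; P is reported in
cm/s (1 nm/ps = 10⁵ cm/s). The ISD model assumes Markovian overdamped
dynamics along z and equilibrium solubility at the interfaces; it ignores
lateral heterogeneity, memory effects and charged-species electrostatics.

## Synthetic data generator

The estimation chain consumes only each window's scalar trajectory z(t), so
the generator replaces the MD engine with overdamped Langevin dynamics on
analytic landscapes. The Euler–Maruyama update of the Itô SDE is

    dz = [ −β D(z) (ΔG'(z) + k(z−c)) + D'(z) ] dt + sqrt(2 D(z) dt) ξ,

where the D'(z) term is the spurious drift required for the stationary
density to be the biased Boltzmann law exp(−β(ΔG + ½k(z−c)²)) when D varies
with position (the test suite verifies both this and the failure mode when
the term is omitted). Trajectories reflect at the support edges ±2.2 nm,
mimicking the bulk-water boundaries of the sampled span.

Default protocol (the study conditions the pipeline is validated under):
22 windows spaced 0.2 nm (centers −2.1…+2.1 nm), harmonic force constant
k = 100 kJ/mol/nm², T = 310 K; single-leaflet protocols use 12 windows
(−2.2…0.0 or 0.0…+2.2 nm) at the same spacing. Windows start at their bias
center; dt = 0.01 ps, 2×10⁵ steps per window, the first 20% discarded as
equilibration, positions saved every 10 steps (0.1 ps). These are
desk-scale stand-ins for production-length MD windows, chosen so the saved
stride resolves the position autocorrelation time (τ = 1/(βkD) ≈ 0.64 ps at
the defaults) while each window still holds 1.6×10⁴ samples. Window i uses
an independent `numpy` Generator seeded `base_seed + i`; windows are
advanced as one vectorized batch that is bit-identical to simulating each
window alone. The integrator refuses dt·D·βk ≥ 0.1 (stability/bias guard).

Preset landscapes on [−2.2, 2.2] nm: `flat`; `gaussian_barrier` (height,
sigma); `square_barrier` (tanh-smoothed walls with a steepness length so
the gradient exists); `membrane_like` — a 12 kJ/mol core barrier with
−4 kJ/mol head-group wells at ±1.3 nm built from quartic-exponent
Gaussians, which keeps the profile C¹ yet float-exactly zero in bulk
(|z| ≳ 2 nm). Diffusivity models: constant (default D₀ = 0.04 nm²/ps, a
typical small-molecule mobility scale in water at body temperature), linear
in z, and a Gaussian dip emulating slowdown in the ordered chain region.

What the generator does *not* emulate: orientational and conformational
solute dynamics, non-Markovian friction, bilayer undulations, finite-size
and pulling-history artifacts, or leaflet-specific chemistry. Passing the
recovery tests therefore shows the *estimators* are correct and internally
consistent at realistic statistics — not that any particular force field or
membrane composition is well described.

## WHAM

Histograms use half-open uniform bins, default width 0.02 nm; samples
outside the binning range are counted as overflow and the solver refuses
overflow ≥ 1%. In single-leaflet modes the histogram range extends 0.6 nm
past the core so the core-centered window's fluctuations across z = 0 are
binned; the half profile is cut at z ≤ 0 (≥ 0) before assembly.

The two self-consistent equations (README) are iterated directly from
fᵢ = 1, gauge-fixed to f₀, until the largest change of −RT ln fᵢ between
sweeps falls below 10⁻⁷ kJ/mol (max 10⁵ sweeps; non-convergence raises with
diagnostics). Bins with zero total count are masked — excluded from
referencing, smoothing and integration rather than interpolated, so no free
energy is invented. Early stopping is *not* monotone in truth error (an
under-converged iterate can sit closer to the truth by luck); what is
monotone, and tested, is the approach to the self-consistent fixed point.

Post-processing order: zero-reference first (mean over the bulk region,
default |z| ≥ 2.0 nm, subtracted; idempotent), then smooth with a centered
moving average spanning 0.05 nm (0.5 Å), truncated at the profile ends.
Leaflet assembly: a symmetric (PS-exposing) membrane duplicates the sampled
leaflet, dG(+z) := dG(−z), exactly mirror-symmetric; an asymmetric membrane
joins two independently referenced halves at the core, additively shifting
the inner half so the profiles meet at z = 0 and reporting the shift as a
core-mismatch diagnostic (the choice of joining rule is ours; the mismatch
magnitude is the honest measure of leaflet consistency). Statistical errors
come from 5-block averaging per window: WHAM is re-solved per contiguous
time block and the between-block standard error reported per bin.

Convergence checking re-solves WHAM on cumulative time slices (e.g. 50%,
75%, 100%) and reports the max |ΔdG| between successive slices over bins
with ≥ 25 total counts in every slice (so the metric measures drift, not
shot noise of barely visited bins); "converged" means the final delta is
below 1 kJ/mol.

## Position-dependent diffusivity

Per window, C_zz(τ) is the biased-normalization (divide by n, so
C(0) = var(z) exactly) autocovariance computed by FFT; a direct double-loop
implementation serves as the test oracle. The integral ∫C dt is trapezoidal,
by default truncated at the first non-positive ACF value — the infinite
upper limit is unimplementable and the noisy tail would otherwise dominate;
the truncation lag is reported and a "full" rule is available. D is
anchored at the window's sample-mean z (with a tilted local PMF that is
where the fluctuations were measured), and per-window values are linearly
interpolated onto the PMF grid with constant extrapolation beyond the
outermost means; the duplicated-leaflet mode folds estimates onto |z| so
the mirrored profile is exactly symmetric. Default max_lag is 50 ps
(≫ τ ≈ 0.64 ps); the model caps it at one tenth of the shortest trace so
reduced runs remain valid, recording the effective value.

Known limitations: the estimator is exact for an Ornstein–Uhlenbeck window
and unbiased at the defaults (single-trace scatter ≈ 9% at 1.6×10⁴
samples), but where D(z) changes appreciably *within* one window the
position ACF becomes multi-exponential and the estimate drifts toward an
effective window average — recovery tests therefore use moderate D
gradients and seed-averaged estimates.

## Permeability

R(z) = exp(βΔG)/D is evaluated on the (by default smoothed) referenced PMF
grid; masked bins propagate and may not lie inside the integration bounds.
R_eff is a trapezoidal integral with bounds snapped to the grid, default
the full sampled span (±2.19 nm of bin midpoints); bulk flanks contribute
negligibly when a barrier dominates, and the bounds are recorded in the
result. exp(βΔG) is smooth at 0.02 nm resolution for barriers ≤ 20 kJ/mol,
so trapezoidal quadrature agrees with adaptive quadrature to well under 1%
(tested). `analytic_permeability` evaluates the same integral on an
analytic truth pair by adaptive quadrature and is the oracle for end-to-end
recovery; log₁₀P is rounded only at report time.

## Structural metrics

Toy bilayer snapshots carry per-lipid head-group triads (three points in
the membrane plane), a z coordinate, per-carbon C–H unit vectors and
masses; the outer (extracellular) leaflet sits at z < 0. Density profiles
are mass histograms over z slabs divided by slab volume (kg/m³). Area per
lipid tessellates the triad centroids (minimum-image centroid of the
wrapped triad) with a Voronoi diagram over a 3×3 periodic replication and
keeps the central-copy polygons — an exact partition of the box, verified
against a nearest-site rasterization oracle. Order parameters are
S_CD = −½⟨3cos²θ − 1⟩ with cosθ the z-component of each unit vector,
averaged per carbon, species and leaflet. Which three atoms form the triad
and whether areas are averaged per frame or per lipid are conventions the
toy generator exposes as parameters rather than fixing.

## Validation summary

The test suite asserts, among others: exact-gradient landscapes;
biased-histogram agreement with the Boltzmann law (χ² on ≥10⁵ decorrelated
ensemble samples); WHAM identity with single-window reweighting
(ΔG = −RT ln n(z) − w(z) + C) to 10⁻⁹ kJ/mol; gauge invariance; recovery of
a 10 kJ/mol barrier to < 0.5 kJ/mol RMS at the default protocol; OU
diffusivity recovery with error decreasing in trace length; ISD closed
forms (P = D/L; sharp square barrier vs analytic resistivity, exact at bin
midpoints because the discontinuity falls mid-cell); end-to-end
|Δlog₁₀P| < 0.3 on the membrane-like landscape; preservation of an imposed
permeability ordering across four mock solutes; and the structural-metric
identities (partition of the box, S_CD = −1/+0.5/0 at θ = 0°/90°/magic
angle). `scripts/acceptance.py` recomputes these headline quantities from
scratch at a caller-supplied seed. Absolute permeabilities of real drug
molecules are outside what synthetic 1-D dynamics can establish; the
reported-table check is confined to its internal P → log P arithmetic.
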