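# memperm

Membrane permeability coefficients from umbrella-sampling time series.

Passive permeation of a small molecule across a lipid bilayer is governed by
the free-energy profile ΔG(z) and the local diffusion coefficient D(z) along
the bilayer normal z. `memperm` implements the standard estimation chain used
in molecular-simulation permeability studies:

1. **WHAM** — the potential of mean force ΔG(z) is estimated from
   harmonically restrained umbrella windows by iterating the self-consistent
   weighted-histogram equations

       ρ(z_b) = Σᵢ nᵢ(z_b) / Σᵢ Nᵢ fᵢ exp(−β wᵢ(z_b)),
       fᵢ⁻¹  = Σ_b ρ(z_b) exp(−β wᵢ(z_b)) Δz,      wᵢ(z) = ½k(z−cᵢ)²,

   followed by bulk-water zero referencing, a 0.05 nm moving-average
   smoothing, and leaflet assembly (duplication of one leaflet for a
   symmetric membrane; joining of two independently sampled leaflets for an
   asymmetric one).

2. **Position-dependent diffusivity** — each restrained window yields a
   local estimate via the variance/autocorrelation relation (Hummer, 2005)

       D(⟨z⟩) = var(z)² / ∫₀^∞ C_zz(t) dt,

   with the position autocovariance C_zz truncated at its first zero
   crossing and per-window estimates interpolated onto the PMF grid.

3. **Inhomogeneous solubility-diffusion (ISD) model** — the permeability
   coefficient is the inverse of the integrated local resistivity

       R(z) = exp(β ΔG(z)) / D(z),    R_eff = ∫_{z1}^{z2} R(z) dz,
       P = 1 / R_eff   (nm/ps → × 10⁵ = cm/s),    β = 1/(R T).

Because the analysis consumes only each window's reaction-coordinate time
series, the package ships a first-class synthetic-data generator: overdamped
(Brownian) Langevin dynamics on analytic ΔG(z)/D(z) landscapes with the
exact biased Boltzmann stationary law, including the ∇D spurious-drift term
needed when D depends on position. The whole pipeline is validated end to
end by recovering the landscapes it was fed. Toy bilayer snapshots and the
standard structural sanity metrics (mass density profiles, Voronoi area per
lipid, deuterium order parameters S_CD = −½⟨3cos²θ − 1⟩) are included for
membrane-model checks.

Intended users: simulation practitioners who want a transparent, tested
reference implementation of the WHAM → D(z) → ISD chain, and method
developers who need a controllable synthetic test bed with known truth.

## Worked example

Simulate a 12-window single-leaflet umbrella protocol on the built-in
membrane-like landscape (12 kJ/mol core barrier, −4 kJ/mol head-group wells,
D = 0.04 nm²/ps) and fit the full pipeline in symmetric-membrane mode:

```sh
memperm run --landscape membrane_like --mode cancer --seed 7 --out demo/
```

which prints

```
          Membrane permeation (ISD model)
=======================================================
membrane mode          cancer
windows                12
temperature            310.0 K
WHAM bin width         0.020 nm (292 iterations)
smoothing span         0.050 nm
bulk region            |z| >= 2.00 nm
integration bounds     [-2.19, 2.19] nm
-------------------------------------------------------
dG_max                   11.538 kJ/mol at z = -0.09 nm
D range                0.0298 .. 0.0410 nm^2/ps
R_eff                          1421 ps/nm
P                             70.38 cm/s
log10 P                    1.85
=======================================================
```

Reading the numbers: the estimated barrier ΔG_max = 11.5 kJ/mol sits at the
membrane core, close to the 12 kJ/mol the trajectories were generated from;
the diffusivity profile stays near the true 0.04 nm²/ps; the integrated
resistivity of 1421 ps/nm inverts to P ≈ 70 cm/s (log₁₀P = 1.85), within
0.06 log units of the exact value for this landscape (log₁₀P = 1.80 by
adaptive quadrature of exp(βΔG)/D). The same artifacts (traces, manifest,
PMF, D(z), R(z), result) are written under `demo/` as headered text files.

The same analysis is available as a library:

```python
import memperm as mp

land, diff = mp.make_reference_landscape("membrane_like")
traces = mp.simulate_protocol(land, diff, mp.half_protocol("outer", base_seed=7))
res = mp.PermeationModel(traces, membrane_mode="cancer").fit()
print(res.summary())          # same table as above
res.pmf, res.diffusivity, res.permeability   # all intermediates
```

Real umbrella-sampling output can be ingested directly: trace files are
two-column (time ps, z nm) text with `#`/`@` comments (GROMACS pullx `.xvg`
dialect), tied together by a TSV manifest of window centers, force constants
and seeds.

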