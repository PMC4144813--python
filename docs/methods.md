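# Methods

This note documents the models implemented in `steroflip`, their
assumptions, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## The bilayer potential

Steroid translocation is reduced to one coordinate: the position z of
the head-group oxygen along the bilayer normal, with the midplane at
z = 0.  The model free-energy surface is even in z (symmetric leaflets),
zero at the equilibrium positions ±z_eq, rises to `dG_center` at the
midplane and to a plateau `dG_desorb` in bulk water beyond
z_water = z_eq + 2·wall_halfwidth.  Three parameterizations:

* **cosine-blend** (default): raised-cosine segments between minimum,
  barrier and plateau.  C¹-continuous, closed-form forces, fully
  determined by (z_eq, ΔG_center, ΔG_desorb, wall_halfwidth).  Note that
  both the barrier-top and well curvatures scale as ΔG·π²/(2 z_eq²).
* **piecewise-harmonic**: parabolic wells clipped at the two cap
  heights.  The well curvature is floored at 2ΔG/z_eq² (inner) and
  2ΔG_desorb/(2·wall_halfwidth)² (outer) so the caps are actually
  reached; the form is C⁰ at the cap joins.
* **tabulated**: linear interpolation of a user grid, for arbitrary
  shapes.

Defaults for the raft-like reference system: z_eq = 1.7 nm,
ΔG_center = 6.4 kJ/mol, ΔG_desorb = 65.4 kJ/mol, wall_halfwidth
0.5 nm — a low midplane barrier and a deep desorption wall, the
signature of a 3-keto sterol in a liquid-ordered mixture.

## Overdamped Langevin dynamics

Trajectories follow the Euler–Maruyama discretization of

    dz = (D/RT)·F(z)·dt + sqrt(2·D·dt)·ξ,   F = −dU/dz.

Inertia is omitted deliberately: every quantity the analysis layer
consumes — stationary densities, free-energy profiles, the barrier
ordering of flip-flop counts — depends only on U(z) and T, not on
momentum details.  The base force is linearly interpolated from a dense
precomputed grid (4096 points), which makes the numba stepping kernel
independent of the potential's functional form; walkers reflect at the
grid edges, well outside the water plateau.  All randomness flows from a
mandatory integer seed; identical specs give bit-identical trajectories.

Defaults: T = 310 K (R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹ throughout),
D = 1 nm²/ns, dt = 10⁻³ ns.  **The diffusion constant is a testing
convenience, not a physical claim**: no value is established for steroid
motion along the normal, and every equilibrium quantity is D-independent.
Kinetic prefactors must therefore never be read off synthetic runs; only
ratios in which the prefactors cancel are meaningful.

## Umbrella sampling and WHAM

The umbrella protocol is fixed by the emulated experiment: 41 windows
spaced 0.1 nm (covering z = 0 … 4 nm one-sided), harmonic restraints of
750 kJ mol⁻¹ nm⁻².  Generator defaults are governed by the stiffness of
that restraint, whose relaxation rate is λ = Dk/RT ≈ 291 ns⁻¹
(τ ≈ 3.4 ps):

* **dt = 5×10⁻⁵ ns** keeps λ·dt ≈ 0.015, so the Euler chain's
  stationary density is unbiased well below the percent level.  The
  sampler was validated against quadrature: window means, variances and
  skewnesses match the exact Boltzmann values within sampling error.
* **90 ns per window, first 10 ns discarded** — within the tens of
  nanoseconds per window of the emulated protocol.
* **samples stored every 10 ps**, leaving a residual autocorrelation of
  ~0.05 so the bootstrap may treat them as independent.  (At 5 ps
  spacing ρ₁ ≈ 0.24 and iid resampling visibly undercovers; a block
  bootstrap with user-set block length is available for correlated
  data.)

WHAM solves the standard self-consistent equations on binned counts.
The implementation is direct iteration augmented with a guarded vector
Aitken Δ² extrapolation: the extrapolated step is accepted only when it
reduces the residual, so the scheme keeps plain iteration's robustness
while cutting its long geometric tail (~3× fewer sweeps at tol = 10⁻⁸ on
the relative change of window free energies; max_iter = 10⁵).  The
fixed point was verified to reproduce the exact binned profile when fed
expected counts.

**Bin width defaults to 0.025 nm** (a quarter of the window spacing).
With k = 750 the windows have σ = √(RT/k) ≈ 0.06 nm, and at 0.05 nm
bins the bias energy varies by ~0.4 RT within one bin, leaving a ~1%
systematic on the recovered barrier; at 0.025 nm the recovery is
bin-converged while every occupied bin still holds hundreds of samples.

Bootstrap errors resample whole observations within each window
(realized as a multinomial redraw of the window's histogram — the same
distribution, since WHAM sees only binned counts) and report the per-bin
standard deviation over n_boot = 200 replicates, each warm-started from
the full-data solution.  Percentile confidence intervals for derived
features are computed from the replicate profiles.

Profiles are referenced to min G = 0; never-visited bins are NaN, not
±∞.  Symmetrization across leaflets is off by default — leaflet symmetry
is a property to *test*, not a processing step.

## Profile features

* z_eq: argmin of G restricted to one leaflet, refined by a parabola
  fitted over the contiguous sublevel set G ≤ min + 1 kJ/mol.  The
  refinement matters: taking the literal lowest bin selects the most
  negative noise fluctuation and inflates both barrier features by
  ~0.1 kJ/mol at test-scale sampling, and a narrow (5-bin) fit is
  noise-dominated in the wide, flat well and behaves no better.  Kinked
  or sparsely resolved minima fall back to the discrete bin.
* ΔG_center = G(0) − G(z_eq), with G(0) linearly interpolated at the
  midplane.
* ΔG_barrier = max G on the path z_eq → 0, minus G(z_eq); it can exceed
  ΔG_center when the barrier top sits off-center, and is never below it.
* ΔG_desorb = mean of G over the declared water region |z| ≥ threshold,
  minus G(z_eq).  Averaging over the plateau (rather than taking the
  endpoint) suppresses end-of-grid noise.

## Flip-flop kinetics

Event detection is a hysteresis two-state automaton: leaflet A while
z ≤ z_low, leaflet B while z ≥ z_high, state kept in between; each A↔B
transition is one event at the first far-threshold crossing.  Thresholds
default to ±z_eq — a flip is complete only when the molecule reaches the
*opposite* equilibrium position, which matches the two-step rate
construction below and suppresses midplane rattling.

The rate model: k_d = 1/t_d (ns → s⁻¹) with t_d supplied as a range —
it is an estimate of the center-to-equilibrium return time, an input,
never fitted from data here; k_f = k_d·exp(−ΔG_center/RT); and
k_flip = ½(k_f⁻¹+k_d⁻¹)⁻¹, with the widely quoted approximation k_f/2
as the default mode.  Published rate tables print two significant
figures, so `round_sig` is provided and comparisons against printed
values are made at 2 s.f.; full precision is always retained.  Some
printed bounds do not round-trip from the printed (rounded) barrier
inputs (e.g. 1/80 ns = 1.25×10⁷ printed as 1.3×10⁷); tests pin only the
self-consistent entries.

**Design of the barrier-ordering experiment.**  To demonstrate that
flip counts follow the Boltzmann factor exp(ΔΔG/RT), the 3 vs 8 kJ/mol
planted potentials use the cosine-blend form with z_eq scaled as √ΔG
(0.8 vs 1.31 nm), which makes the well and barrier-top curvatures equal
(23.1 kJ mol⁻¹ nm⁻²) in both systems.  Equal curvatures mean equal
Kramers prefactors, so the count ratio isolates the Boltzmann factor;
with equal z_eq the curvature (∝ ΔG/z_eq²) would enter the prefactor as
the ratio 3/8 and — together with the sizeable diffusive (barrier-free)
share of the transit time at βΔG ≈ 1.2 — push the measured ratio down to
~2.6–3.9, obscuring the effect under test.  At 1500 ns per run both
systems produce ample events (≈ 870 and ≈ 130 on average).

## Membrane observables

* **S_CD** = ½⟨3cos²θ−1⟩ with θ between the C–H vector and the membrane
  normal, pooled over both chain hydrogens of a carbon *before*
  averaging (the alternative — per-hydrogen averages first — differs
  only at the fourth decimal for realistic samples but is stated here
  for definiteness).  Profiles report |S_CD| with the signed value
  retained; the standard error is over per-lipid means.
* **Hydrogen bonds**: donor–acceptor distance ≤ 0.325 nm AND
  angle(D→A, D→H) ≤ 35°, both inclusive.  The angle is between the
  donor→acceptor vector and the donor→hydrogen covalent-bond vector —
  *not* the H–D–A or D–H⋯A convention of some packages; this is stated
  prominently because the criteria are not interchangeable near the
  cutoff.  Charge pairs: oppositely charged atoms within 0.4 nm
  (inclusive).
* **MSD**: all overlapping time origins, per-lag pair counts reported.
  Optional per-leaflet center-of-mass removal subtracts each leaflet's
  per-frame mean position, cancelling monolayer drift at the cost of a
  (1 − 1/n_tracks) scale factor, negligible at the track counts used.
  D_L is the least-squares MSD slope over a user lag window divided
  by 4; the intercept is free, so constant offsets do not bias D.
* **Area per lipid**: time-averaged box area divided by lipids per
  leaflet, reported in Å² (1 nm² = 100 Å²) with its standard deviation.

## Laurdan GP

GP = (I_ord − g·I_dis)/(I_ord + g·I_dis) per pixel.  The G factor
multiplies the disordered channel — the convention of the common ImageJ
macro; since the corrected formula is rarely written out, the factor is
configurable and recorded in every result.  The reference GP used to
calibrate g (Laurdan in pure DMSO) is a user input, not a constant.
Pixels with raw summed intensity below the mask threshold (default 5% of
the 99th-percentile summed intensity) are excluded before any
statistics.  Normalization to control supports both difference (default)
and ratio modes, declared in the output — which of the two a given
study used is often ambiguous, so neither is asserted.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the analyses
assume: Boltzmann-distributed biased windows, prescribed orientation
order, exact planted geometries, Brownian lateral motion, and
shot-noise-limited two-channel images.  Passing tests therefore
demonstrate that the estimators are correct and well-calibrated on data
obeying their assumptions.  They do not show anything about force-field
accuracy, finite-size or sampling artifacts of real MD, membrane
undulations (the bilayer here is flat and rigid), probe photophysics, or
cell heterogeneity — and measured per-system observable values (H-bond
averages, areas per lipid, order-parameter profiles of real mixtures)
require the original trajectories, which no formula layer can replace.

## Numerical details and edge cases

* Readers reject rather than coerce: non-monotone times, NaNs, missing
  headers and length mismatches fail naming the offending row; Å/ps
  headers are converted on read.  Profile TSVs round-trip float64
  exactly (17 significant digits).
* Empty histogram bins are NaN everywhere; features raise if the water
  region or midplane is uncovered.
* WHAM refuses non-overlapping adjacent windows (naming the gap) and
  reports the residual on non-convergence.
* Series time-uniformity is checked to 1e-9 relative with an ULP-scale
  floor for long trajectories (adjacent differences of n·dt carry
  rounding of order ulp(t)).
* The flip-count and parameter-recovery checks run at reduced problem
  sizes (1500 ns runs, 90 ns windows, 200 bootstrap replicates, 10
  seeds) chosen so their statistical resolution comfortably exceeds the
  effect sizes under test.
* Pipeline outputs carry a config digest and seed; reruns with identical
  stages and seeds are byte-identical, and existing outputs are never
  overwritten without `--force`.
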