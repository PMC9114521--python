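# Methods

`depstretch` models an automated dielectrophoretic (DEP) single-cell
stretcher: a microfluidic chip that traps single cells at an array of
capture ports, stretches them with a nonuniform AC field, measures the
length change on video, and releases them for the next batch.  The
package covers the electromechanics, the electrode-field and hydraulic
models of the chip, a synthetic device simulator, and the population
analysis that turns length traces into strains and Young's moduli.

## Electromechanics

A homogeneous dielectric sphere (radius r, complex permittivity
ε\*_p = ε_p − jσ_p/ω) in a medium ε\*_m experiences the time-averaged DEP
force

    F_DEP = 2π r³ ε_m Re(f_CM) ∇E²_rms,
    f_CM  = (ε*_p − ε*_m) / (ε*_p + 2 ε*_m),

with ω = 2πf (the standard DEP convention; adopted and documented here
because frequency-vs-angular-frequency is a common ambiguity).  Re(f_CM)
is bounded in [−0.5, 1]: the infimum is reached by an insulating
particle in a conductive medium at low frequency, the supremum by a
highly conductive particle in a near-insulating medium.  For the
single-relaxation sphere the crossover frequency has the closed form

    f_c = (1/2π) √( −(σ_p−σ_m)(σ_p+2σ_m) / ((ε_p−ε_m)(ε_p+2ε_m)) ),

which exists exactly when the conductivity-dominated and
permittivity-dominated limits of Re(f_CM) differ in sign; the
implementation cross-checks it against root bisection in the tests.
Only the homogeneous sphere is modelled: multi-shell membrane models,
ellipsoidal depolarisation factors and electrorotation are out of scope.

The stretching stress on a trapped cell is summarised as

    σ_stress = n Re(f_CM) ε_m E0²,        E = σ_stress / ε,

where n is a dimensionless constant of the electrode geometry and E0 a
reference field.  We read n as |E|·r·(d|E|/dx)/E0² — the unique
dimensionally consistent form that keeps n dimensionless and σ in Pa —
with x the stretching axis through the capture port and E0 defaulting to
(applied voltage)/(smallest electrode gap).

## Field solver

n comes from a 2D finite-difference Laplace solve on the electrode
plane (the channel height, 25 μm, is uniform, so a 2D section is an
acceptable approximation).  Five-point stencil, Dirichlet values on
rasterised electrode nodes, mirror (zero-normal-flux) outer boundaries,
direct sparse factorisation.  Verified against two closed forms: a
parallel-plate capacitor (uniform |E| = V/d; n = 0) and a coaxial
quarter-annulus (|E| ∝ 1/r; d|E|/dr = −|E|/r; with E0 taken as |E| at
the evaluation point, n = −r_cell/r_point).  At a grid spacing of
gap/100 the |E| error against the annulus solution is below 1% at
mid-annulus points; errors grow near the rasterised (staircase)
electrode boundaries, so evaluation points should stay a few grid cells
away from electrodes.  The discrete maximum principle (interior
potentials bounded by electrode potentials) holds by construction and
is asserted on every tested solve.  The bundled demo geometry is a
facing-tips electrode pair across an 18 μm capture-port gap.

## Trap-array hydraulics

At low Reynolds number each rectangular channel segment is a hydraulic
resistor,

    R = 12 μ L / (w h³ [1 − Σ_{k odd} (192 h)/(k⁵π⁵ w) tanh(kπw/2h)]),

(h ≤ w; series truncated at k = 99, which agrees with k = 9999 to 1e−6
at the worst aspect ratio).  The chip is a ladder network: a 100 μm main
channel with 10 capture ports per side at 100 μm pitch, each port a wide
(18 μm) plus narrow (6 μm) segment in series, bridging to two 100 μm
bypass channels; boundary ports are the cell inlet (CI), release outlet
(RO) beside it, and buffer inlet (BI)/waste outlet (WO) downstream.
The bypasses dead-end upstream and rejoin the main channel at the
downstream junction — the layout that produces the observed strictly
decreasing per-port pressure difference in forward flow, and that
isolates the bypasses entirely when every port is blocked.  Segment
lengths outside the trap region (inlet 500 μm, RO branch 1000 μm,
WO/BI branches 300 μm, port segment lengths 10 μm each) are defaults:
they are not derivable from the published channel widths, so the model's
agreement with the chip's CFD study is qualitative — order of magnitude
and monotonicity, not point values.  With these defaults the first-port
Δp at 3 μL/h is ≈1.1 Pa (CFD: 1.6 Pa) falling to ≈0.03 Pa (CFD: 0.1 Pa),
and ≈16% of the release flow re-enters the capture area (CFD: ~1/10).

Kirchhoff solves use nodal analysis with a boundary map of fixed-flow
and fixed-pressure nodes (capture mode: inflow CI, RO and WO at 0 Pa;
release mode: inflow BI, RO and WO at 0 Pa).  A captured cell blocks its
port via a ×1e6 resistance multiplier (configurable, since real cells
seal imperfectly).  Re-solving after blocking shows every same-side port
gains Δp while far opposite-side ports can shed a few percent as flow
redistributes toward the release-outlet branch — so "blocking never
decreases Δp anywhere" is an idealisation that holds per side, not
globally; the tests assert the verified version.  Deflectors, entrance
losses, bends and full Navier–Stokes behaviour are outside the lumped
model.

## Strain and modulus analysis

Strain uses the min/max rule: ε = (L_max − L_0)/L_0 with L_0 and L_max
the extreme detected lengths of a trace, irrespective of order.  The
shared stretching stress comes from either

* calibration mode (default): σ = E_ref·ε_ref from a reference
  (modulus, strain) pair — the worked examples use (203.7 Pa, 0.0864),
  giving σ = 17.59968 Pa, and the independent second cell type's pair
  (257.3 Pa, 0.0684) gives 17.59932 Pa, identical to four significant
  figures, which is why a single shared stress is assumed; or
* physics mode: σ = n·Re(f_CM)·ε_m·E0² with n from the field solver.

QC excludes (and itemises) traces with non-finite or non-positive
lengths, zero strain (valid but unmeasurable: no modulus), and broken
cells, flagged when the minimum length falls below 0.5× the starting
length (configurable).  Group reports give n, mean, median, a central
75% interval (the 12.5th–87.5th percentiles — our reading of a
"75% confidence interval" box range), a group modulus σ/mean-strain,
and proportions per half-open strain interval (default width 0.03 up to
0.09 plus an overflow bin).  Moduli are presented to one decimal in Pa;
files carry full precision.  No significance test is performed: the
report is descriptive, and the per-cell tables are exposed for callers
who want their own inference.

## Synthetic device simulator

The simulator emulates the study conditions so every pipeline stage is
testable without hardware:

* **Capture**: independent categorical draws per port per round
  (none/single/multiple), keyed by narrow-mouth size; the 6 μm default
  is p = (0.10, 0.842, 0.058).  The single-capture probability 0.842 is
  the bead-characterised efficiency of the selected mouth size; the
  none/multiple split is our choice, as only the single-capture value is
  published numerically.
* **Populations**: lognormal true strain (defaults: means 0.0864
  normal / 0.1013 treated, CV 0.6 — wide, matching the broadly spread
  single-cell strain scatter), lognormal resting length (15 μm, CV 0.1,
  bead-sized cells), broken-cell probability 0.02 ("a small number"
  break; no published number), and a first-order saturating stretch
  response L(t) = L₀(1 + ε(1 − e^{−t/τ})) with τ = 2 s — the simplest
  creep law consistent with a rise to plateau; the true law is not
  published and τ is configurable.
* **Detection noise**: Gaussian, sd 0.02 μm per frame (sub-pixel jitter
  of a box detector at 0.24 μm/px optics).
* **Controller**: capture rounds until the fresh single-cell count
  reaches the threshold (default 10 of 20 ports; the published trigger
  is a count threshold without a number), then a 10 s stretch sampled at
  50 fps (exactly 501 frames), then release with efficiency 1.0 by
  default (the bead experiments released essentially everything at
  150 μL/min).  Un-released cells stay in place, are never re-measured,
  and block their ports for later cycles.

One seeded `numpy.random.Generator` drives an entire run; the seed is
recorded in the event log, and seeded reruns are byte-identical at the
file level.

### What the simulator does not emulate

Pixel-level imaging and detection (traces begin at detected lengths),
cell arrival hydrodynamics (capture rounds are count-triggered, not
kinetic, so simulated throughput is not a prediction), electro-
deformation physics (the stretch curve is phenomenological), and any
coupling between a cell's dielectric properties and its stiffness.
Passing recovery tests therefore shows the *pipeline* is unbiased and
correctly plumbed under the stated generative model — not that the
generative model is the truth of any real cell population.

## Estimator bias and the recovery tolerance

The min/max strain estimator is positively biased under noise (it takes
extremes over ~500 noisy frames) and negatively biased by finite τ
(the plateau is only reached to 1 − e^{−T/τ}; −0.7% at τ = 2 s,
T = 10 s).  A Monte-Carlo oracle of the estimator at the default
conditions (n = 1000 cells/group) measures a net bias of about +2.5 to
+4% relative with a replicate SD of ≈1.9% — the SD is dominated by the
population CV (0.6/√1000), not the noise.  The end-to-end recovery check
therefore uses a tolerance of 10% relative (≈ bias + 3 SD); a 5%
tolerance is not attainable at these conditions even with noiseless
traces, since 3 SD alone exceeds it.  With noise and time constant
switched off and zero population variance, recovery is exact to machine
precision and is tested as such.

## Numerical choices

* Vacuum permittivity ε0 = 8.8541878128e−12 F/m; conductivities in S/m
  (unit strings like "50 uS/cm" are converted on config load: 1 μS/cm =
  1e−4 S/m); flows internally in m³/s (1 μL/h = 2.78e−13 m³/s).
* DEP regime sign tolerance: |Re(f_CM)| ≤ 1e−12 is "null".
* Field solver: direct sparse LU; Laplace residual at interior nodes is
  machine-precision and asserted < 1e−12 of the potential span.
* Water viscosity 1.0e−3 Pa·s.
* Half-open strain bins [lo, hi); values ≥ the upper edge go to the
  overflow bin; bin edges are multiples of the bin width.
* Degenerate inputs: traces shorter than 2 samples, empty groups after
  QC, zero-electrode geometries, disconnected networks and unreachable
  capture thresholds raise typed errors naming the offending input.

## Problem sizes

Default verification sizes were chosen to characterise each component
well on a laptop: 1e5 random parameter evaluations for the CM-factor
bounds, 221×221 grids for the field-solver oracles, the full 20-port
network for hydraulics, 1e4 ports for capture statistics, 1000
controller cycles for the state-machine check, and 1000 cells/group for
recovery.
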