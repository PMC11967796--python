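# Methods

This note records the models implemented in `spindrop`, the assumptions
behind them, the defaults that matter, and the choices made where the
design was genuinely open. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Centrifugal hydraulics (`physics`)

The aqueous column between the free surface (radius R₁ from the rotation
axis) and the nozzles (radius R₁+R₂) is treated as rigid-body rotating
liquid; integrating the body force ρω²r over the column gives the driving
pressure ½ρω²((R₁+R₂)² − R₁²). This assumes the nozzles are aligned with
the oil surface so no oil back-pressure term appears, and neglects gravity
(centrifugal accelerations here are hundreds to thousands of m/s²).

The capillary pressure of a rectangular channel is the Young–Laplace jump
2γcosθ(1/w + 1/h): negative for hydrophobic walls (θ > 90°), which then
oppose filling. The channel resistance uses the classical rectangular-duct
series solution. Two conventions are fixed deliberately:

- **Series orientation.** The series converges only with the smaller
  cross-section dimension in the role of the height, so the implementation
  always evaluates with h := min(w, h), w := max(w, h). This also enforces
  the physical w↔h symmetry. The bracket factor is 0.42173 for a square
  duct (giving the familiar 12/0.42173 ≈ 28.5 constant) and tends to 1 in
  the parallel-plate limit; it deviates from 1 by roughly 0.63·h/w, so the
  slab formula is accurate to 1% only for aspect ratios ≳ 60.
- **Truncation.** Terms are added until one contributes less than a
  relative tolerance (default 1e-12, ≲ 50 odd terms); tolerances above
  1e-3 are rejected as meaningless.

Flow through a channel is V_in = (P_aqu + P_cap)/(R_hyd·w·h). A
non-positive pressure sum yields zero velocity with a `no_flow` flag rather
than an error: this state occurs legitimately when a hydrophobic channel
stalls near the end of sample depletion.

**Regime heuristic.** The Weber number ρV_in²D_h/γ on the hydraulic
diameter D_h = 2wh/(w+h) separates periodic dripping (monodisperse) from
the dripping faucet (polydisperse). No sharp universal boundary exists; the
default threshold is 1.0 (order-one inertia/capillarity crossover),
configurable, with the boundary value assigned to the faucet side. This is
a flagged heuristic, not a fitted constant.

Units are SI internally; `from_lab` constructors and the CSV schema accept
µm, mm, rpm, mPa·s, mN/m and degrees, since instrument settings arrive in
those units.

## Sample depletion (`depletion`)

The reservoir is modelled as a liquid column of constant free-surface
cross-section A_res whose surface recedes radially outward as n identical,
synchronized channels drain it: R₂(V) = V/A_res, R₁(V) = R_noz − R₂(V).
Real reservoirs are not perfect prisms; this is the simplest geometry
consistent with a surface-height-dominated driving pressure, and the trace
is exact for it. The volume ODE dV/dt = −n·w·h·V_in(V) is smooth and
non-stiff, so a classical fixed-step RK4 integrator is used, with the step
halved (up to five times) until the end velocity changes by less than
0.1% of the begin velocity. Runs terminate at V ≤ 1e-4·V₀ (avoiding
division noise at the empty limit), at an optional time cap, or when the
velocity falls below 1e-6 of its initial value — a hydrophobic channel
approaches its stall volume asymptotically, and below that cutoff the
remaining flow is physically meaningless.

## Droplet-size predictor (`predictor`)

The resistance factor R_f = 2γ(1/w + 1/h − 2/D)/V_in lumps the hydraulics
of the neck connecting the channel exit to the growing droplet, with the
neck flow approximated by the inlet flow rate (adopted as-is, no
correction term). At fixed centrifugal acceleration, R_f follows
R_f = α·e^(−βD) across channel sizes and flow rates.

- **Fitting** is ordinary least squares of ln R_f on D. The factors span
  orders of magnitude, so log-space fitting stabilizes the variance and
  has a deterministic closed-form solution; whether the underlying
  relationship should be fitted in R_f or ln R_f is not decidable from
  first principles, and log space is the documented choice. At least three
  observations with positive R_f are required per acceleration group;
  groups are clustered at 1% relative acceleration tolerance
  (accommodating floating-point ingest of rotor settings).
- **Prediction** equates the two R_f expressions. On (2wh/(w+h), ∞) the
  left side rises strictly from zero and the right side is positive and
  strictly decreasing, so at most one root exists. The solver certifies a
  sign change on [D_floor(1+1e-6), 1 mm] before running Brent's method
  (absolute tolerance 1e-12 m, far inside the 1 nm that matters
  physically), and refuses conditions outside the periodic-dripping
  regime, where the law does not apply.
- **Untrained accelerations** raise an error by default. An optional
  interpolation mode treats ln α and β as piecewise-linear in acceleration
  strictly inside the trained span; it is an extension beyond the
  per-acceleration fits and is only used when explicitly requested.
- **Evaluation** splits the dataset 2:1 into training and validation,
  stratified by acceleration with seeded shuffling, and reports the mean
  absolute relative diameter error over validation points.

## Pre-design (`designer`)

Tiled droplets are budgeted with a square-footprint rule: each droplet of
diameter D occupies a D×D square, the square-minus-circle margin serving
as spacing, so the circle area available in a reservoir of area A (with a
fraction optionally reserved as tiling headroom) is A·(1−reserve)·π/4.
With N = 6V/(πD³) droplets from a sample volume V, the accumulated circle
area is 1.5V/D, giving D_min = 1.5V/budget; a minimum droplet count gives
D_max = (6V/(πN_min))^(1/3). Both bounds invert their defining constraints
exactly, and the library returns unrounded values — display rounding is
the caller's business. An explicit budget override lets a user supply an
externally rounded budget verbatim instead of the rule-derived one.
Hexagonal or other denser packings are deliberately out of scope: the
square-footprint rule is the one the budgeting convention is built on.

Reverse engineering is an exhaustive grid search (channel catalogue ×
angular-velocity grid, default 500–6000 rpm in 100 rpm steps): each
condition is resolved, regime-checked, predicted, and either returned as a
candidate (sorted by distance to the window midpoint) or rejected with a
reason. Candidates re-validate independently under `predict_diameter`.

## Digital-assay statistics (`assay`)

This module works in the units assay practitioners use (droplet volumes in
µL, concentrations per µL), while the physics layers are SI.

- **Global threshold:** mean of negative-control intensities + 3 sample
  SDs. Without a control, a self-referential variant starts from the
  droplets below the intensity mid-range (isolating the negative mode even
  near saturation) and iterates mean+3SD over current negatives to a fixed
  point.
- **Local classification:** two passes. Provisional labels from the global
  threshold; then each droplet is re-tested against mean + 5 SD of its 10
  nearest provisionally-negative neighbours. "Surrounding" is interpreted
  as nearest by 1-D scan-order position (5 per side where available),
  matching stitched-image traversal; no 2-D geometry is assumed. A
  zero-SD neighbourhood falls back to the global threshold for that
  droplet; fewer than 10 provisional negatives overall falls back to
  global labels with a warning flag. "Exceeds" is read strictly: a droplet
  exactly at threshold is negative. All thresholds are built from means
  and SDs, so the classification is invariant under affine intensity
  rescaling applied consistently to droplets and controls.
- **Poisson quantification:** C = −ln(1−p)/V, undefined at p = 1
  (saturated assay). An optional Wilson score interval on p can be
  propagated through the inversion; it is an extension beyond the point
  estimate. Dilution linearity is OLS on log10–log10 pairs; the LOD is the
  lowest concentration positive in all replicates; the MIC is the lowest
  tested antibiotic concentration with droplet survival at or below a 10%
  cutoff.

## Synthetic data (`synth`)

The generators emulate the *structure* of a centrifugal step-emulsification
study, not any particular measured dataset.

- **Condition grid:** 3 square channel sizes (20/30/40 µm, 5 mm long) × 5
  accelerations (1500–6579.7 m/s²) × 4 rotor geometries that share each
  acceleration but split the liquid column differently (R₂ = 4–7 mm at a
  fixed 24 mm nozzle radius), hence varying the flow rate — 60 conditions,
  each acceleration stratum holding 12 points so a 2:1 split leaves
  enough to fit. The synthetic aqueous phase is water-like (ρ = 1000
  kg/m³, µ = 1 mPa·s) with γ = 5 mN/m and θ = 120°.
- **Truth law:** ln α linear in acceleration, β with a mild linear trend
  (ln α = 12.9 − 3.0e-4·a; β = 9500 + 0.48·a m⁻¹). These are synthetic
  choices, tuned once so the grid spans mean diameters of roughly
  118–396 µm inside the 80–400 µm envelope, with the two
  highest-acceleration 40 µm conditions tipping into the dripping-faucet
  regime and being skipped — the same shape a real dataset shows.
- **Observation noise** is lognormal at two levels sharing the default 1%
  scale: a condition-level scatter of the mean diameter about the law
  (run-to-run reproducibility — without it, averaging 1000 droplets would
  shrink the mean's noise to ~0.03% and validation errors would be
  vacuous) and a per-droplet spread that produces the reported CV.
- **Fluorescence populations:** occupancy ~ Poisson(C·V); intensity =
  baseline 100 + drift·sin(2π·index/500) + N(0, 3), plus a shift of 100
  for occupied droplets; default drift amplitude 10 (10% of the
  separation). True labels are retained for accuracy scoring.

What passing tests on these data do and do not show: they verify the
estimators recover parameters under the stated noise model (lognormal
size noise, Gaussian intensity noise, sinusoidal drift, ideal Poisson
loading). Real data add effects not modelled here — partitioning bias,
droplet coalescence and shrinkage, amplification failure in occupied
droplets, focal-plane intensity gradients beyond periodic drift — so
accuracy figures on synthetic data bound the method's numerical behaviour,
not its wet-lab performance.

## Problem sizes and determinism

The test suite and acceptance script use the 60-condition grid, 10⁴-point
brute-force diameter scans (100 random conditions), 12 500-droplet
populations with 3 replicates per concentration, and 5000-droplet drift
stress tests; these sizes make every statistical margin comfortable (e.g.
three binomial standard errors at the lowest assayed concentration) while
keeping any single check in the seconds range. The assay-recovery check
spans 28.5–2850 copies/µL: with 145 µm droplets (1.6 nL) the Poisson assay
saturates above ~3×10³ copies/µL, where ~37 500 droplets no longer contain
enough negatives to invert p reliably. All randomness flows through
`numpy.random.default_rng` with caller-supplied seeds; identical seeds give
identical outputs, including byte-identical CSV exports.

## Known limitations

- No CFD: the flow field, meniscus shapes and neck dynamics are absorbed
  into the resistance-factor law; the library cannot predict α and β from
  first principles, only fit them.
- The regime threshold is heuristic, and the law's validity near the
  dripping-faucet onset is not quantified.
- The depletion model assumes a prismatic reservoir and identical,
  synchronized channels; per-channel variability is out of scope.
- The assay layer starts from extracted intensities; image processing
  (circle detection, stitching, focal correction) is out of scope, and the
  only drift correction is the local-neighbourhood rule itself.
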