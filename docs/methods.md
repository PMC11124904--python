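# Methods

This note records the models, conventions and numerical choices behind
`circumkin`, and what the synthetic experiments do and do not demonstrate.

## Conventions

Time is minutes from recording start; the nominal frame interval is 3 min
(0.0056 Hz). Positions are mm in axes (X, Y, Z) with Y vertical; every
planar quantity (turning angles, centers, areas) lives in the X–Z plane.
Leaf windows — the interval from tendril emergence to support contact or
collapse — are supplied as metadata, not detected from images; gaps in
sampling are tolerated and reported, never interpolated. The PRE/POST
phase boundary is 5000 min (the passage from the second to the third
leaf), with the boundary itself belonging to POST. The last three leaf
windows per plant, ordered by start time, carry the ranks "Third last",
"Second last", "Last".

## Loop segmentation

The per-loop measures require cutting a leaf's planar path into
individual revolutions, a step with several free choices:

* **Winding criterion.** The signed turning angles between consecutive
  displacement vectors are summed while walking the path; a loop closes at
  the first sample where |Σθ| since the previous closure reaches
  2π − *slack*. The signed sum telescopes — it equals the heading change
  of the displacement vector plus complete windings — so frame-to-frame
  noise does not accumulate along a loop. A sum-of-|θ| criterion would be
  upward-biased under noise and was rejected.
* **Slack.** A sampled open revolution is always a couple of angular steps
  short of 2π, so the closure slack adapts to the observed median step
  (2.5 steps, clipped to [0.3, 1.0] rad). After each closure the winding
  residual is carried over, keeping successive closures phase-locked to
  the underlying revolutions.
* **Smoothing.** Turning angles are computed on a lightly smoothed copy of
  the path (centered moving average, 9 samples = 27 min, with quadratic
  extrapolation past the path ends so no turning is lost at the edges).
  Without it, the heading of the sub-millimetre displacements of early
  small-amplitude loops is dominated by positional noise and the winding
  count degenerates into a random walk. The window is well below the
  fastest default circumnutation period (90 min), so the winding itself is
  unaffected. All reported measures (turning sums, centers, areas, speeds)
  are computed from the raw samples of each detected range; only boundary
  detection uses the smoothed path.
* **Reversals.** A turning angle of magnitude > 2 rad is treated as a
  direction-reversal cusp: the turn through a cusp carries no winding
  information (its sign is numerically arbitrary), it always terminates
  the current loop, and winding is never carried across it. Loops ending
  at a cusp or at the path end receive an extra closure allowance
  ((window + 2) median steps, clipped to [0.3, 1.2] rad) because smoothing
  flattens about half a window of turning on each side of a boundary.
* **Direction rule.** Each loop's raw turning sum s is classified
  counterclockwise iff |s − 2π| ≤ 1.2 rad, clockwise iff |s + 2π| ≤ 1.2,
  else no direction; ties at the edges fall in the directional class. A
  switch is a change of non-none direction between consecutive loops,
  attributed to the new direction; undetermined loops never generate
  switches.

The trailing partial loop of a window is discarded. With the defaults,
loop recovery on noiseless simulations is exact, and at per-axis noise of
5% of the loop radius the count is within ±1 per leaf in ≥ 90% of trials
(both are asserted in the test suite).

## Dependent measures

Speeds use the full 3D displacement (‖Δp‖/Δt), since the organ climbs
while circumnutating; a planar variant would ignore real motion.
Acceleration is the first difference of speed over midpoint spacing
(mm/min²), i.e. a scalar tangential acceleration. The circumnutation
center is the coordinate-wise mean of the loop's planar points and its
distance from the plant origin is planar Euclidean. Area is the raster
footprint of the loop's polyline — every 1-mm grid cell the curve passes
through (supercover rasterization, computed exactly by cutting each
segment at its grid-line crossings) — not the filled interior. Note the
footprint of a closed curve of length L on cells of side h is
≈ (|dx|+|dz|)/h summed along the curve (about 4/π · L/h for a circle),
not L/h. Movement time is the leaf window span.

## Statistical stage

All factors are coded sum-to-zero, the condition required for Type-III
Wald tests to be meaningful; responses (and GAM predictors) are z-scored
over the observations entering each model.

* **Linear mixed models** are fitted by REML through statsmodels'
  `MixedLM`, with a per-plant random intercept and, when requested, a
  random slope for the experimental condition. Because condition is a
  between-plant factor, the intercept/slope decomposition is not
  identifiable: such fits sit on a likelihood ridge, are flagged
  `singular`, and are refitted with the intercept-only structure (whose
  marginal model is the identified content of the specification). When
  the variance sits on the boundary the default optimizer can fail; the
  fit cascades through optimizers until the covariance is usable.
* **Type-III tests** are Wald χ² of a term's coefficient block against its
  covariance block (`χ² = c′V⁻¹c`, df = block size). A singular block —
  e.g. after complete separation of a count cell — raises in the
  functional API and yields a NaN row (with a warning) in summary tables.
* **Estimated marginal means** average the encoded design over the full
  factorial of the remaining factors with equal weights; pairwise
  contrasts use z = estimate/SE with a Tukey (studentized-range,
  asymptotic df) familywise adjustment. Both choices are the common
  defaults for post-hoc contrasts of factorial mixed models; the
  adjustment is configurable in principle by consuming the raw z values.
* **Cross-index GAM.** The additive model y = f(x) + controls + a_plant + ε
  uses a cubic B-spline basis of dimension 10 with a second-difference
  penalty, rewritten in mixed-model form (penalty null space → fixed
  intercept and linear term; whitened wiggles and per-plant intercepts →
  two variance components). Both smoothing parameters maximize the REML
  criterion (profiled σ², Woodbury identities, Nelder–Mead from several
  starts). The smooth's edf is the trace of its block of the influence
  matrix (1 for the linear part in the heavy-penalty limit). Significance
  is assessed by an exact F test of the *unpenalized* spline basis against
  the model without f(x) (holding the plant ridge fixed): unlike an F
  ratio on penalized residuals, this keeps the null distribution of p
  uniform, which the suite verifies by simulation. Under the null the
  reported edf is occasionally inflated on a single draw (REML finding a
  spurious wiggle); the suite therefore checks the median over replicates.
* **Poisson GLMM.** Switch counts are modelled with a log link and a
  per-plant Gaussian random intercept integrated out by a Laplace
  approximation (per-group 1-D Newton for the conditional mode, then BFGS
  over fixed effects and log τ²; covariance from a central-difference
  Hessian). Fixed effects agree with the R reference implementation
  (`glmer`) to ~10⁻³ on shared fixtures, which the suite asserts.
* **Descriptive splines.** `bspline_curve` least-squares fits a cubic
  B-spline basis with 3 degrees of freedom (interior knots at quantiles
  when df > 3); the basis contains all lines, so linear data are
  reproduced exactly.

## Synthetic data

`simulate_plant` emulates the study's qualitative structure: five leaves,
the first two (PRE) small and slow (radius 5–8 mm, period 300 min), the
later three (POST) larger and faster (radius 18–30 mm, period 150→90 min),
windows scheduled so the third leaf starts after the 5000-min boundary;
linear vertical growth (0.03 mm/min); per-loop direction flips with
configurable probability; for supported plants the last leaf's center
closes a configurable fraction of the gap to the support (12 cm in front
of the plant); i.i.d. Gaussian positional noise per axis (default
0.5 mm, settable per leaf). Amplitudes and periods are not published for
the study plants, so these defaults are plausible placeholders — chosen
once for a realistic contrast between phases, not calibrated to any
recording. Tendrils are simulated from the third leaf as a scaled,
phase-shifted copy of the apex motion.

`simulate_cohort` draws the per-circumnutation table directly from its
statistical model (cell means × multiplicative effects, a shared additive
per-plant intercept and observation noise on a fixed per-index scale,
Poisson loop counts, Bernoulli direction flips), which makes calibration
studies (size, power, recovery) fast. Its additive, homoscedastic
random-intercept structure is exactly what the mixed models assume — by
design, since its purpose is to test that machinery at the study's scale
(16 supported + 8 unsupported plants). Zero-loop leaves are emitted as
zero-count rows with missing per-loop indices.

What passing tests show — and what they do not: the pipeline recovers the
generator's ground truth and the inferential stage is correctly calibrated
under the generator's assumptions. Real recordings have features the
generator lacks (irregular amplitudes and periods, tracking dropouts,
non-Gaussian marker error, drifting centers on every leaf), so the tests
validate the software and its statistical calibration, not biological
conclusions.

## Problem sizes

The simulation studies use the cohort design throughout (24 plants,
~30 circumnutations each): 300–500 replicates for test size, 100 for
power and loop-recovery rates, 10-cohort averages for reported estimated
marginal means and rate ratios, and n = 600 for GAM checks. These sizes
give Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

* Lens distortion, calibration estimation and image-based tracking are out
  of scope; stereo starts from ideal pinhole cameras and 2D tracks.
* The loop segmentation assumes roughly convex loops at the 3-min cadence;
  heavily re-entrant paths between reversals would be split differently.
* The GLMM supports a single random intercept (the study's structure);
  nested or crossed random effects are not implemented.
* Tukey adjustment uses asymptotic (infinite-df) studentized range;
  small-sample Kenward–Roger-style corrections are not attempted.
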