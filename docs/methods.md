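# Methods

## Cantilever mechanics

Each post is treated as a linear-elastic Euler–Bernoulli cantilever loaded
at its tip: F = k δ with k = 3πED⁴/(64H³).  Units are μm for lengths, nN
for forces and Pa for the modulus; k is reported in N m⁻¹ (1 N m⁻¹ =
1000 nN μm⁻¹) and the μm→nN conversion happens once, at the deflection
step.  The built-in generations are gen1 (E = 3.8 MPa, D = 4 μm, H = 15 μm,
blocks 15×15 μm footprint, 25 μm tall) and gen2 (D = 6 μm, H = 25 μm,
blocks 25×25 μm footprint, 15 μm tall); the gen2 block dimensions are read
as footprint×height in the same ordering as gen1.  Large-deflection
corrections, substrate warping and fluid drag on the post are neglected:
drag deflections are below 0.1 μm even at the highest shear rates used,
which also justifies treating the first frame as the undeflected reference.

Flow configuration uses the infinite-parallel-plate wall shear rate
γ̇ = 6Q/(wh²) and its algebraic inverse.  The exact rectangular-duct series
solution is deliberately out of scope; a warning is raised when the channel
aspect ratio w/h falls below 10, where the approximation degrades.  No
channel cross-section preset ships because none is fixed by the device
design; users supply w and h.

## Image pipeline

**Detection.**  The structural channel (DiI-stained elastomer) is
Otsu-thresholded; connected components at least a quarter of the expected
block footprint count as blocks, smaller compact components as posts.  Each
post pairs with its nearest block within 0.45× the array pitch; unpaired
features are reported, never dropped.  Ties break by nearest distance, then
raster order, so detection is deterministic.

**Localization.**  Subpixel positions come from an intensity-weighted
centroid after subtracting the window median and zeroing pixels below three
robust standard deviations (1.4826×MAD) of the local background, evaluated
twice: once in the search window (three post diameters), then in a tight
window (one post diameter) recentred on the first estimate.  The second
pass removes most of the background-noise contribution to the centroid
variance; at the generator's default brightness the per-frame localization
noise is ≈ 0.03 px.  The centroid was preferred over Gaussian fitting
because it degrades gracefully when an aggregate partially occludes the
post top; a Gaussian-fit refinement is available behind the
``gaussian_fit`` config flag and performs equivalently on clean spots.

**Drift registration.**  Blocks are rigid and stationary, so stage drift is
estimated from block windows only, by subpixel phase cross-correlation of
each block window against frame 0 (upsampling factor 100), averaged over
blocks; a centroid-based fallback exists.  The drift model is rigid
translation only — adequate for stage drift at high magnification —
and residual block motion is reported as a QC metric.  Frames without a
usable block get interpolated offsets and a warning.

**Deflection sign convention.**  Image coordinates are x-right/y-down with
pixel centres at integers.  Deflection is the projection of the
drift-corrected tip displacement onto the unit vector from the post's rest
position toward its block centroid; positive means toward the block
(contractile).  Frames with an empty or saturated window are invalid and
carry no force; a track over 50% invalid is unusable.  Forces are never
interpolated across gaps.

**Segmentation.**  The aggregate-free reference frame is subtracted first —
the faint DiI bleed-through of blocks and posts into the calcium channel is
constant per frame, so the difference isolates the aggregate.  Each
difference frame is Otsu-thresholded within a window spanning the
block→post axis; the largest connected component is kept after small-object
removal and hole filling.  A frame whose foreground rises less than
8 intensity units (or 4 robust noise sds) above the residual background is
declared aggregate-free with area 0, flagged — never silently zero-filled.
Manual polygon tracings can replace the automatic mask; rasterised polygon
areas agree with the shoelace formula within a one-pixel border.

**Calcium.**  The per-frame mean fluo-3 intensity inside the aggregate mask,
minus a constant background taken as the first-frame median outside the
site window (the DiI bleed-through is constant and cancels).  Empty-mask
frames yield missing values, not zeros.

## Traces and endpoints

Usable tracks of one field of view are linearly resampled onto a uniform
grid at the median frame interval (no extrapolation; interior invalid
frames stay missing and are dropped per timepoint).  The trace is the
per-timepoint mean with SEM = sd/√n, undefined below two sites.  Traces are
not baseline-subtracted by default since the rest-frame definition already
zeroes deflection; an optional first-value subtraction exists.  Endpoints
are linear interpolations of the mean trace at the assay time (default
120 s); requests outside the trace span are errors.  Percent inhibition is
100×(control − treated)/control per quantity.

## Cohort statistics

Classical tests are delegated to scipy/statsmodels behind a stable surface:
two-sided paired and unpaired t, one-way ANOVA with Tukey HSD
(Tukey–Kramer for the unbalanced 10/17/93 groups), Shapiro–Wilk as the
documented normality gate, Pearson correlation, chi-square.  Degenerate
inputs (zero-variance differences, constant groups) are flagged explicitly
rather than producing division-by-zero artifacts.  The test suite pins all
of them to values frozen from an independent R session (t.test, aov +
TukeyHSD, shapiro.test, cor.test, chisq.test, glm-binomial) on fixed
fixtures.

The transfusion model is a binomial GLM fitted by IRLS (statsmodels; 100
iteration cap, deviance tolerance 1e-10).  The ROC AUC is the rank
(Mann–Whitney) estimator with midrank ties, computed on the fitted scores —
identical to ranking the raw predictor under the monotone link, hence
invariant to increasing predictor transforms, and exactly U/(n₁n₀).  The
unit odds ratio is exp(slope) per +1 nN, reported with its Wald CI and as a
percent odds change; per-effect p-values in the multivariate model come
from likelihood-ratio tests refitting without one term.  Complete
separation yields AUC 1.0 plus a warning rather than a crash.  p-values are
never truncated internally, and no multiple-testing correction is applied
beyond Tukey.

## Synthetic data

**Movies** emulate a staggered sensor array imaged at 0.2 Hz.  Blocks are
rendered as PSF-blurred squares, posts as Gaussian spots (σ = 1.5 px) at
rest + deflection positions, with uniform-random subpixel placement so
localization is actually exercised.  The per-site force follows a logistic
curve anchored to zero at t = 0 (default terminal force 100 nN, half-rise
60 s, slope 0.08 s⁻¹, 10% site-to-site amplitude scatter); ground-truth
forces equal stiffness × deflection exactly by construction.  The aggregate
is a growing ellipse (eccentricity 0.7, final area 500 μm²) anchored at the
block's downstream face; its calcium-channel brightness is a resting dye
level (40 counts) plus a gamma-shaped transient peaking at 0.4× the force
half-rise time — encoding that intracellular calcium rises before
contraction.  Noise is Poisson shot noise plus Gaussian read noise
(sd 2 counts) over a background of 10 counts, with post peak amplitude 400
and block amplitude 250 — conservative for a cooled CCD imaging a
dye-stained elastomer; drift is a constant per-frame translation.  The
renderer is a pure function of (spec, seed): identical specs give
bit-identical movies.  Specs whose terminal deflection would exceed half
the block-to-post gap are rejected at validation.

Movie-based checks use 31 frames at 5 s (2.5 min of assay, covering the
120 s endpoint) and fields of 1–4 sensors; the method is strictly per-site,
so small fields measure the same thing as the full arrays at a fraction of
the rendering cost.

**Cohorts** draw per-subject endpoint forces from per-group normals
truncated at zero by rejection sampling (truncation mass ≈ 2% for the
default parameters, which lifts the realised group means by ~2–3 nN —
tests compare against the analytic truncated mean).  Defaults are the
trauma-study groups: 10 healthy at 148.2 (44.4) nN, 93 non-transfused at
122.9 (60.1) nN, 17 transfused at 82.8 (40.5) nN, outcome assigned by
group.  Prehospital-fluid rates are the published 63%/76%; hematocrit
means/sds are not published and are set to plausible clinical values
(0.43/0.41/0.37, sd 0.03–0.06) — they matter only as confounder
placeholders, not as estimands.  The closed-form binormal AUC
Φ(|μ₂−μ₁|/√(σ₁²+σ₂²)) ≈ 0.710 for the trauma groups serves as the oracle
for the empirical ROC.

## What the synthetic benchmark does and does not show

Passing recovery tests shows the pipeline is unbiased and precise for
well-separated, rigid-geometry sensors with Gaussian-spot posts, constant
bleed-through, pure-translation drift and elliptical aggregates.  Real
movies add complications deliberately not modelled: partial occlusion of
post tops by dense aggregates, non-elliptical and fragmenting aggregates,
focus drift and photobleaching, red-cell shadowing, and camera-specific
noise.  The statistical results on synthetic cohorts exercise the
estimators, not the biology: they show that *if* group forces follow the
published distributions, the logistic-ROC machinery reproduces the
published discrimination (replicate-mean AUC ≈ 0.716, percent odds decrease
≈ 1.6% per nN against the published 0.72 and 1.4%) — the per-+1 nN odds
slope is steeper than published because the fitted single-slope logistic
compromises between the two groups' unequal variances, for which the true
log-odds is quadratic in force.

## Numerical choices and edge cases

- Logistic fits: IRLS, max 100 iterations, tolerance 1e-10; non-convergence
  raises with diagnostics.
- Rank AUC uses midranks, exact to 1e-12 against U/(n₁n₀) without ties.
- Trace resampling never extrapolates; endpoint times outside the span are
  errors.
- Detection on a blank frame returns an empty result with a log message,
  not an exception; a lone block yields an unpaired-block diagnostic.
- All randomness flows through numpy Generators seeded from explicit spec
  fields; reruns with identical config and inputs produce bit-identical
  result files (the run manifest, which records wall-clock timings, is the
  one intentionally non-reproducible output).

## Known limitations

Single-post force reconstruction within an aggregate is out of scope, as
are 3-D reconstruction, phase-contrast-only tracking, fluid–structure
simulation of the block/post flow field, and kinetic model fitting to
experimental traces.  The drift model has no rotation or scale terms.  The
segmentation threshold is global per window; heavily textured backgrounds
would need a local method.
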