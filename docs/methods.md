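# Methods

This note documents the models and procedures implemented in `gazecross`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Geometry and units

All thresholds are in degrees of visual angle; all stored coordinates are
0-based screen pixels (origin top-left), timestamps in ms, event intervals
half-open `[t_start, t_end)`. Two conversions coexist deliberately:

* Reported extents (e.g. the full monitor) use the exact centred-chord
  formula `2·atan(extent_mm / (2·distance_mm))`. With the default geometry
  (1920 × 1080 px, 521 × 293 mm, 600 mm) this gives 46.9° × 27.4°.
* Per-sample displacements use the local linear factor at screen centre,
  `deg/px = degrees(mm_per_px / distance_mm)` (0.0259 deg/px horizontally).
  For sub-5° extents the two differ by < 1%, and sample-to-sample
  displacements at 1000 Hz are far below that.

The small-angle factor mildly *under*-estimates true angular velocity away
from the screen centre; at the ±23° eccentricities reachable on this
monitor the error stays below ~8% and does not move samples across the
50 deg/s threshold in practice.

## Event parser

Velocity is estimated by central differences of x and y over time
(one-sided at the stream ends), converted per axis with the centre factor,
combined as the Euclidean norm, and smoothed with a centred moving average
of 20 ms (21 samples at 1000 Hz). Samples adjacent to invalid (blink)
samples have undefined velocity. The estimator and window are our choice —
the velocity computation is not further specified by the thresholds alone —
and 20 ms suppresses 1000 Hz jitter noise (which otherwise reaches tens of
deg/s per sample) without blunting saccade peaks of 200+ deg/s.

Classification proceeds in bands:

1. speed > 50 deg/s → saccade (maximal runs);
2. speed ≤ 30 deg/s sustained ≥ 100 ms (inclusive) → smooth-segment
   candidate;
3. the intermediate band (30, 50] deg/s, and sub-threshold runs shorter
   than 100 ms, default to fixation.

Candidates are scored by `P_RMSE / exp(A)`: quadratics are fitted to x(t)
and y(t) after one pass of robust outlier removal (drop samples whose
Euclidean fit residual exceeds the median + 3 MAD-based SDs), `P_RMSE` is
the RMS residual pooled over both axes, and `A` is the arc length of the
fitted 2-D curve integrated by the trapezoid rule on a dense grid. Both are
in **pixels**: with the 10⁻⁹ decision threshold, pixel-scale arc lengths
(tens to hundreds of px for true pursuit, a few px for fixation jitter)
make the discriminator behave sensibly, whereas degree-scale arc lengths
(A ≈ 1–5 for real pursuits) would not separate the classes. When A exceeds
~709, exp(A) overflows float64; the score is then computed as
`P_RMSE · exp(−A)`, which underflows to exactly 0 — the intended limit.

Two guards handle degenerate candidates: segments with fewer than
`poly_degree + 2` valid samples stay fixation, and candidates whose net
displacement is below 10 px stay fixation regardless of score (a perfect
noiseless fixation fits with zero residual and would otherwise be labelled
pursuit). Fixation runs shorter than 40 ms that border a saccade are
absorbed into it: the velocity smoothing otherwise leaves few-millisecond
intermediate-speed slivers at saccade flanks that no oculomotor taxonomy
would call fixations.

Quality control: a trial is removed iff **strictly more than 50%** of its
valid samples exceed the saccade threshold; a participant is excluded iff
strictly more than 50% of their trials are removed. Both inequalities are
strict, so exactly-half cases are retained.

Segments partition each trial's span `[t₀, t_last + dt)` exactly; at
1000 Hz every sample contributes 1 ms, and the per-label totals plus
missing time reconstruct the trial duration to the millisecond.

## Gaze maps and similarity

Valid sample positions are binned on the screen grid downsampled 4× (480 ×
270), smoothed with an isotropic Gaussian of SD 1° (≈ 38.6 px / 4 ≈ 9.7
cells), and z-scored over cells. Smoothing-then-z-scoring vs the reverse is
immaterial for Pearson correlations (affine invariance); downsampling is
harmless because the 1° kernel removes all structure below ~40 px.
Correlations are clipped to |r| ≤ 1 − 10⁻⁶ before the Fisher transform so
duplicate maps stay finite (z ≈ 7.25).

The consistency curve averages each trial's Fisher z to all other trials,
per participant, then across participants, and sorts descending.
Confidence intervals are percentile bootstrap with the **participant** as
the resampling unit (1000 resamples by default); with a single participant
the CIs degenerate to the point estimate (with a warning). CI bounds are
clamped to bracket the point estimate so small bootstrap samples cannot
produce inverted intervals.

## Pixel-wise statistical mapping

Instead of a per-pixel linear mixed model with random intercepts for
participant and stimulus, maps are first averaged within participant ×
condition cells and an ordinary linear model (treatment coding, intercept +
main effects, plus the tested interaction's columns when requested) is
fitted per pixel on the cell means. Under a balanced design this two-stage
summary-statistics scheme gives the same fixed-effect F tests as the mixed
model with a participant random intercept, at a tiny fraction of the cost
and with no convergence failures. F for an effect is the extra-sum-of-
squares statistic comparing the full and reduced designs (computed through
orthonormal bases of the two column spaces, so the bootstrap refits cost
two small matmuls per draw).

Cluster correction: the cluster-forming threshold is the pointwise
(1 − α) F quantile; clusters are 8-connected suprathreshold components
summarised by their **mass** (sum of F over the cluster — more sensitive
than extent alone). The null distribution of the maximum cluster mass is
built by refitting on effect-removed residual maps whose participants are
resampled with replacement within their between-factor stratum, preserving
the design; a cluster is significant when its mass exceeds the (1 − α)
quantile of that null. Resampling residuals keeps the participant block
structure (the analogue of the random intercept) while satisfying the null.
The pairwise contrast map is a pooled-variance two-sample t on participant-
mean maps with the same correction applied to |t|. Significant areas are
reported rescaled to full 1920 × 1080 pixel units (mask cells ×
downsample²).

Calibration and sensitivity are verified by simulation in the test suite:
across 20 null simulations (two groups of 8 participants, unit-variance
noise smoothed with a 3-px Gaussian, 480 × 270 grid, 200 bootstrap draws)
at nominal α = 0.05 the observed familywise error stays within the ≤ 0.10
acceptance band, and a planted focal group difference (d = 2 inside a
20-px-radius disc, 10 participants per group) is recovered with Jaccard
overlap ≥ 0.5.

## Decision statistics

* **k-means**: scikit-learn's KMeans with k-means++ seeding and
  `n_init = 1000` restarts (the "1000 iterations to verify the centroids
  group consistently" is read as restarts, which is what stability
  verification requires); the best run by within-cluster sum of squares
  wins, centroids are reported sorted ascending.
* **Yuen's test**: trimmed means with γ = 0.2 by default (floor(γn) removed
  per tail), winsorized variances, Welch–Satterthwaite df. At trim = 0 it
  reduces exactly to Welch's t (verified to 10⁻¹⁰). The effect size is an
  explanatory (ξ-type) measure — the SD of the trimmed-mean "prediction"
  over the winsorized SD of the pooled data — reported as `d`; it is 0 for
  identical trimmed means, grows with separation, and is symmetric in the
  samples.
* **Shift function**: Harrell–Davis estimates of the nine deciles (beta-cdf
  weights over order statistics; the weights depend only on n and the
  quantile, so bootstrap resamples reuse one weight matrix), differences
  x − y, and percentile-bootstrap CIs resampling each sample independently
  (1000 draws by default). Simulated coverage of true decile differences is
  ≈ 95% (0.957 measured over 200 replicates at n = 100 per group).
* **Density split**: `fixed:c` labels a trial high iff count > c (default
  cut 3: dense means more than 3 vehicles on screen). The `kde` rule places
  the threshold at the *centre* of a Gaussian KDE (Silverman bandwidth) of
  the counts, defined as the half-mass point of the smoothed density. For
  two balanced traffic regimes this falls in the trough between them (≈ 3
  for mixed Poisson(1.5)/Poisson(5.5) counts); a mode-based definition was
  rejected because the Silverman-bandwidth KDE of such counts is typically
  unimodal with its peak inside the low-traffic regime, which is not a
  usable dichotomisation point.

## Traffic density

A per-pixel online mixture of K = 3 Gaussians (Stauffer–Grimson style)
models the background: the best-matching component within 2.5 SD absorbs
each sample with learning rate 0.02; unmatched pixels replace their weakest
component with a fresh one centred on the sample. A component is background
when its weight reaches 0.4 (the top-weight component always is) — a
per-component dominance rule chosen over the classical cumulative-weight
rule because transiently-tracked foreground objects (vehicles re-visiting
the same pixels) must not graduate into the background. All state is
initialised from the first frame, which makes counting exactly invariant to
a global brightness offset. Foreground masks are cleaned by 3 × 3
morphological opening, labelled with 8-connectivity, and components smaller
than `min_area_px = 30` are discarded (this is also what excludes the small
pedestrian blob). Per-frame counts start after a 25% warm-up of the clip;
the per-trial vehicle count is the **maximum** simultaneous count, matching
the "more than N vehicles on screen" dichotomisation downstream.
Overlapping vehicles merge into one blob — a documented limitation of
connected-component counting.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not the visual
content of real recordings:

* **Scanpaths**: 10 s trials at 1000 Hz. Fixations are static anchors with
  isotropic Gaussian jitter (SD 0.5 px ≈ 0.013°, an optimistic precision
  for a tower-mounted tracker); pursuits are linear drifts at 8–16 deg/s
  along the road heading; saccades are ballistic transitions with a
  triangular velocity profile, 30–60 ms duration and ≥ 180 px amplitude
  (peak velocity > 200 deg/s). Consecutive events are always joined by a
  saccade so ground-truth boundaries are recoverable; when the spatial bias
  is so tight that no supra-threshold saccade is possible, the fixation is
  extended instead. Real data additionally contain drift, microsaccades,
  tracker noise bursts, blinks and curved pursuits — the parser's
  ground-truth recovery rate (≥ 95% of samples at default noise; ~99%
  measured) is therefore an upper bound on real-data performance, and the
  tests characterise algorithmic correctness, not field accuracy.
* **Cohorts**: three groups whose gaze-bias mixtures shift mass from the
  vehicle appearing point (upper-left road entry) toward the sidewalk band
  and vehicle-following pursuits as age decreases, with wider anchor
  scatter for younger groups. Decision counts are normal, rounded, floored
  at 0; the two child groups use the reported cluster parameters (means 8
  and 13, SD 1) and adults share the older children's distribution, since
  those groups were reported not to differ. Press durations are log-normal
  around 1 s (shape 0.4) — a generic right-skewed choice.
* **Traffic clips**: 120 grayscale frames at 240 × 135 (a scaled-down
  screen), static textured background, vehicles as bright rectangles
  entering at a fixed appearing point and travelling along the road line at
  constant speed, staggered so all co-occur in the second half of the clip;
  optional pedestrian as a small slow blob on the sidewalk band; additive
  Gaussian pixel noise (SD 0.01).

All generators are deterministic given a seed.

## Problem sizes

The analysis drivers run a scaled cohort (3 × 5 participants, 30 trials)
and the statistical mapping uses an 8× downsampled grid with 300 bootstrap
draws; the test suite uses 480 × 270 or smaller grids, 100–300 bootstrap
draws, 100–2000 Monte-Carlo replicates per calibration study, and 100
k-means replicates of 30 + 30 participants. These sizes were chosen so the
whole pipeline re-runs in minutes while keeping every Monte-Carlo check
adequately powered; all of them are parameters, not constants.

## Known limitations

* The two-stage statistical mapping matches mixed-model fixed-effect
  inference only for (near-)balanced designs; unbalanced cell structures
  raise an explicit error in the residual bootstrap rather than silently
  reweighting.
* The parser assumes a fixed head (screen-centre conversion); head-free or
  3-D extensions are out of scope.
* Blob counting cannot separate overlapping vehicles and is validated on
  staggered trajectories.
* The KDE density split assumes the count distribution has either one
  regime or two; with more regimes the half-mass point is still defined but
  no longer an antimode.
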