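# Methods

## The measurement

On a ventrodorsal hip-extended (VDHE) radiograph, canine hip dysplasia (CHD)
shows up in the proximal femur as bone modeling: osteophyte and exostosis
formation widens the radiographic silhouette of the femoral neck until, in
severe disease, neck and head become hard to distinguish. The femoral neck
thickness index quantifies this:

* **FHd** — femoral head diameter, the diameter of a circle fitted to
  landmarks placed on the femoral head margin;
* **FNT** — minimal femoral neck thickness, the shortest chord joining the
  two closest points between the proximal and distal neck-margin traces;
* **FNTi = FNT / FHd** — a unit-free ratio, so no pixel-spacing calibration
  is needed and dogs of different sizes are comparable. Higher values mean
  a thicker (more modeled) neck.

The **Norberg angle** (NA) is measured at a femoral head centre between the
line to the contralateral head centre and the line to the ipsilateral
effective cranial acetabular rim; it feeds the FCI (Fédération Cynologique
Internationale) A–E grading.

### Geometry implementation

* **Circle fit** — algebraic least squares (Kåsa): minimise
  Σ(x² + y² + Dx + Ey + F)², a closed form with no iteration. For exactly
  three non-collinear points it is the circumcircle. This is accurate for
  the near-complete arcs an examiner places on a head margin; a geometric
  refit (Gauss–Newton on orthogonal distances) is available via
  `method="geometric"` for short, noisy arcs, where the algebraic fit is
  known to shrink the radius slightly.
* **Minimal neck thickness** — exact minimum distance between the two
  margin polylines over all segment pairs, including point-to-segment
  projections, with the realizing point pair returned. Ties are broken
  toward the smallest (proximal, distal) segment indices so the output is
  deterministic. Intersecting margins mean an invalid annotation and raise
  an error rather than returning zero. The radiographic convention that
  the thickness chord runs roughly perpendicular to the neck axis is
  available as an opt-in `axis_constraint` (degrees of admissible deviation
  from the perpendicular of the mean margin direction; 30° is a reasonable
  tolerance). It is off by default because the unconstrained closest-point
  rule is the operational definition of the measurement.
* **Norberg angle** — atan2 of cross/dot products; unsigned, in [0, 180),
  invariant under translation, rotation, uniform scaling and mirroring, so
  left and right hips share one code path.

All coordinates use the image convention (origin top-left, y down), units
arbitrary but uniform per image. FNTi and NA are dimension-free, so every
downstream statistic is too.

## Rule-assisted FCI grading

The published FCI criteria combine NA with qualitative judgements
(congruency, osteoarthritic signs, head centre vs. dorsal acetabular
margin) and overlap between grades — the moderate grade's "NA > 90°" also
holds for every better grade. `assign_grade` therefore evaluates worst
criterion first (E → A) and takes every qualitative flag as an explicit
input; it is an *assist*, not a replacement for expert scoring, and every
threshold is configurable. "Around 105°/100°" bands default to ±2°.
Combinations no published rule covers (e.g. a benign joint with NA 95°)
fall back to NA bands (≥103° → B, ≥98° → C, >90° → D, else E), which keeps
the classifier a total function and monotone: at fixed flags, a smaller NA
never yields a better grade.

## Agreement statistics

For matched measurements of the same hips (two sessions of one examiner,
or two examiners), differences are first-listed minus second-listed.

* **Bland–Altman**: mean difference d̄, SD of differences (n−1), 95%
  limits of agreement d̄ ± 1.96·SD (literal 1.96, not a t quantile), and
  the t-based 95% CI of d̄. Per-unit (mean, difference) pairs are emitted
  for plotting; no plotting engine is required.
* **Paired t**: t = d̄/(SD/√n), df = n−1, two-sided. All-identical pairs
  flag the result degenerate instead of dividing by zero.
* **Cohen's d**: pooled-SD variant by default (|x̄₁−x̄₂| / √((s₁²+s₂²)/2));
  a paired-difference variant (|d̄|/SD_d) is selectable and the report
  names the variant, since the two can differ considerably when the
  within-pair correlation is high. Bands: negligible < 0.20 ≤ small
  < 0.50 ≤ medium < 0.80 ≤ large.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — computed from the two-way ANOVA mean squares, with the
  F-based McGraw–Wong confidence interval. This is the standard model for
  a measurement method whose raters are interchangeable; ICC(3,1)
  (consistency) is available. Reliability is judged on the *lower* 95%
  bound: poor < 0.50 ≤ moderate < 0.75 ≤ good < 0.90 ≤ excellent.

## Grade-group comparison

Per-grade screening uses Shapiro–Wilk (normality) and Levene's test
(variance homogeneity; classic mean-centred by default, median-centred
Brown–Forsythe selectable) — both delegated to scipy, as they are standard
tests. Because grade variances differ, the omnibus test is **Welch's
heteroscedastic ANOVA** (weights wᵢ = nᵢ/sᵢ², Welch's F with
Satterthwaite-style df2), followed by the **Games–Howell** post hoc
procedure: per pair, SE = √(sᵢ²/nᵢ + sⱼ²/nⱼ), Welch–Satterthwaite df, and
the adjusted p from the studentized-range distribution at |t|·√2 with k
groups (scipy's `studentized_range`; with k = 2 this reduces exactly to
the two-sided Welch t-test, which the tests assert). α = 0.05 two-sided
throughout.

Significance patterns are rendered as a **compact letter display** via the
insertion–absorption algorithm: groups in ascending-mean order, letters
split on each significant pair and absorbed when redundant, so two groups
share a letter iff their pair is not significant — including
non-transitive patterns. Letters are assigned deterministically along the
mean order.

Each hip joint is treated as an independent observation; there is no
dog-level clustering correction. This mirrors common screening practice
but understates uncertainty when both hips of a dog enter the sample — see
limitations.

## Synthetic data

No radiographs or raw measurements are distributed, so two seeded
generators emulate the study conditions.

**Cohort generator.** True FNTi per grade is truncated normal with
per-grade (mean, SD, n) defaulting to the study structure — A: (0.809,
0.024, 19), B: (0.835, 0.044, 23), C: (0.868, 0.022, 24), D: (0.903,
0.033, 24), E: (0.923, 0.068, 16), 106 hips — truncated to (0.70, 1.05),
bounds chosen to bracket the observed global range (0.757–1.036). The
configured moments are treated as the *observed* moments of the bounded
index: when a truncation bound bites (grade E's upper bound sits at ~1.9
SD), the generator solves for the pre-truncation location and scale whose
truncated distribution has exactly the configured mean and SD, so every
grade reproduces its nominal moments by construction. A
`intra_dog_correlation` knob (default 0, hips independent) lets the two
hips of one dog share a normal dog effect.

**Examiner error model.** Observed = true + bias + Gaussian noise,
additive and homoscedastic by default. Calibration: intra-examiner
difference SD 0.019 ⇒ per-session noise 0.019/√2 ≈ 0.0134; inter-examiner
difference SD 0.021 ⇒ second-examiner noise √(0.021² − 0.019²/2) ≈ 0.0161;
biases 0 / +0.001 / +0.007 reproduce difference means −0.001
(session 1 − session 2) and −0.007 (examiner 1 − examiner 2). A
`heteroscedasticity` knob (default 0) can inflate noise for thicker necks,
whose intricate osteophyte-laden contours are harder to delineate.

**Scene generator.** Landmark-level only (no pixels): boundary points on a
circle of the requested head diameter, two *waisted* neck margins —
narrowest directly below the head, flaring parabolically toward head and
shaft, as a femoral neck does — whose minimal separation is exactly the
requested FNT at the waist vertex pair, and rim/contralateral landmarks
realizing the requested Norberg angle exactly. Optional Gaussian landmark
jitter models annotation error; ground truth is returned alongside. The
waisted shape matters: on long parallel margins the closest-point rule
takes a minimum over many equivalent chords and jitter biases it downward,
whereas a localized waist keeps the jittered measurement nearly unbiased.

All randomness flows from one master seed through `numpy.random
.SeedSequence` spawning (one child stream per grade / per examiner
stream), so outputs are bit-reproducible and streams are independent.

### What passing tests on synthetic data do and do not show

The generators reproduce the study's first and second moments, its group
sizes, and its examiner difference structure. They do not reproduce:
within-dog correlation of left/right hips (default off; the real sample
has 2 hips per dog), any heteroscedasticity of examiner error, non-normal
shape detail, or the qualitative flags' joint distribution with NA.
Consequently, synthetic results validate the *statistical machinery* and
the *calibration targets*, not raw-data-dependent quantities. One concrete
consequence: simulating independent hips at the published group moments
makes the C–D contrast significant in ~95% of replicates and C–E in only
~50%, so the published superscript pattern {a, ab, bc, cd, d} is
essentially never produced; the corresponding acceptance test documents
this and fails honestly rather than tuning the generator toward the
printed letters.

## Numerical choices

* Circle fit solved via `numpy.linalg.lstsq` on centroid-shifted
  coordinates for conditioning; collinearity detected by the second
  singular value (≤ 1e−10 relative).
* Norberg angle via atan2, clamped into [0, 180).
* ICC confidence bounds clamped to [−1, 1]; zero between-unit variance
  raises an explicit "ICC undefined" error.
* Degenerate paired data (zero difference SD) flags the t-test and
  paired-difference effect size as degenerate rather than emitting NaNs.
* Studentized-range p-values clipped to [0, 1] (the scipy survival
  function can stray by ~1e−16).
* Full precision is stored everywhere; the pipeline's `report_precision`
  (2 or 3 decimals) affects only formatted report strings.

## Problem sizes

Stochastic checks use: 20 000 draws per grade for moment recovery; 500
replicates of the 106-hip cohort for the omnibus rejection rate, examiner
SD calibration, and bias/limits recovery; 200 replicates for post hoc
patterns and downstream ICC ranges; 1000 random patterns for the
compact-letter property; 100 jittered scenes for geometry robustness.
These sizes give Monte-Carlo error comfortably below the tolerances
asserted.

## Known limitations

* The grading assist encodes only the NA thresholds and explicit flags;
  real FCI scoring weighs aspects (joint space, acetabular shape, OA
  detail) that are not modelled.
* Hips are treated as independent in the group comparison; a mixed model
  or clustered bootstrap would be the rigorous alternative and is noted as
  future work in report text only.
* The scene generator produces landmark coordinates, not images; it cannot
  exercise landmark *placement* behaviour, only the geometry downstream of
  it.
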