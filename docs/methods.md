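# Methods

`stilkit` implements a complete desk-scale model of a digital-pathology
reader study for stromal tumor-infiltrating lymphocyte (sTIL) scoring in
breast cancer: the score itself, the calibration of its constant, the
multi-reader agreement statistics, the automated-assistance revision
workflow, and the downstream neoadjuvant-chemotherapy response analysis.
Everything runs on synthetic whole-slide data produced by the package's own
generator, so every pipeline stage is testable without image data.

## The sTIL score

A region's sTIL score is

    sTIL% = α · N / (A / U)

where `N` is the number of detected lymphoid cells on cancer-stroma pixels,
`A` the cancer-stroma area in μm², and `U` an area unit. The score converts
point detections into an area-coverage percentage: treating a lymphoid cell
as a disk of radius r = 3 μm, the exact geometric coverage is
`100·π·r²·N/A`. With `U = 400 μm²` the implied multiplier is
`100·π·9/400 ≈ 7.068`, which is why α ≈ 7 is the natural constant. Field
descriptions of this scoring scheme do not state the area unit that makes
α ≈ 7 dimensionally sensible; this package fixes `U = 400 μm²` as the
unique convention under which the conventional constant and the
3-μm-sphere rationale coincide, and makes `U` configurable and logged.

Scores are clamped to [0, 100] for reporting; calibration and diagnostics
see the raw (unclamped) value. A zero-stroma region raises an error rather
than silently scoring 0. The score satisfies an exact pooling identity —
the score of a union computed from summed counts and areas equals the
area-weighted pooling of any partition — which the tests exercise on random
partitions.

### α calibration

`calibrate_alpha` mirrors the grid-panel procedure used to fix the
constant: square grids are randomly cropped from slides, a rater panel
scores each grid, grids not scored by every rater (or with no stroma) are
excluded, and each candidate α ∈ {6.5, 7.0, 7.5} is evaluated by Lin's
concordance correlation coefficient (CCC) between the equation's grid
scores and the panel mean — overall and restricted to low-score ranges
(panel mean < 10, < 15, < 20). Selection maximizes overall CCC; ties break
toward the better < 20-range CCC and then toward the smaller α. This
tie-break formalizes the qualitative requirement that the chosen constant
be "balanced" between whole-range and low-range agreement.
`calibration_study` replicates the experiment end-to-end: per replicate,
249 grids of 128 px at 2 μm/px are cropped from five slides whose lymphoid
densities follow a fixed geometric ladder (0.3–3.2 × 5000/mm²), so the
grid library spans the low-to-high score range the way a calibration set
drawn from many whole-slide images does; three unbiased geometric raters
score each grid (true coverage × mean-one lognormal noise, log-sd 0.1).
The noise is mean-corrected because the selection criterion is scale
sensitive: the CCC-optimal scaling between the equation score and a
noisy panel mean is the RMS of the noise factor, so even a fraction of a
percent of mean bias in the raters systematically drags the selected
constant upward. With unbiased raters the selection concentrates on 7.0,
the candidate nearest the geometric multiplier 7.068, and the study
reports the modal α over 100 seeded replicates.

## Synthetic data generator

The generator emulates four data streams. What it does *not* emulate is
listed under limitations.

**Tissue maps.** A smoothed Gaussian random field (correlation length
200 μm by default) is rank-thresholded: the top `cancer_fraction` of pixels
become cancer area, the next `stroma_fraction` cancer stroma, the rest
background. Realized fractions are exact to the pixel. Default scale is
2 μm/px; default study slides are 1.2 × 1.2 mm. These desk-scale rasters
stand in for whole-slide segmentations; the physical-scale conventions
(coordinates in μm, origin top-left, y downward, pixel = floor(coord/mpp))
are uniform across the package.

**Cell point patterns.** Lymphoid cells follow an inhomogeneous Poisson
process restricted to stroma: per-pixel Poisson counts with mean
density × pixel area × a relative intensity field, then uniform placement
within pixels — an exact sampler at raster resolution. The relative field
is `exp(h·G)` with `G` smoothed unit-variance Gaussian noise and `h` the
`heterogeneity` parameter (log-scale SD; 0 = homogeneous Poisson),
normalized to mean 1 over stroma so the expected count is preserved. This
doubly stochastic construction is the simplest process with a tunable
clustering knob, chosen to reproduce the spatially heterogeneous lymphocyte
infiltration that drives inter-rater discordance. Tumor cells are
homogeneous Poisson in the cancer area. The default lymphoid density in
the full study is lognormal per slide (median 5000 /mm², log-sd 0.8),
giving a cohort whose true sTIL spans the low/intermediate/high strata
with a mean around 20%.

**Pathologist raters.** A rater samples `k_fields` (default 8) square
visual fields of 300 μm centred on stroma, computes each field's true
geometric coverage, multiplies by lognormal noise (log-sd 0.3–0.45 across
the default panel), averages, applies multiplicative and additive bias
(defaults −6 to +5 points, mimicking panel members who systematically read
low or high), rounds to a 5-point grain and clamps to [0, 100]. With all
error terms zero and a field covering the slide, the rater returns the
truth up to rounding — the noiseless limit the tests pin down.

**Automated reader.** Each true lymphoid cell is kept with probability
`lymphoid_recall` (default 0.90); false positives are added uniformly over
stroma at `false_positive_rate` (default 1750 /mm²); the stroma mask is
degraded by adding a smooth random field to the (lightly smoothed) mask
indicator and re-thresholding at the area-preserving quantile, with the
amplitude found by bisection so the realized IoU against the true mask
hits `mask_iou_target` (default 0.666) within ±0.005; if a noise draw
makes the target unreachable the search retries with a fresh field, and a
genuinely unattainable target produces a warning plus the realized value.
The sTIL score is then computed from the degraded outputs exactly as for
real model output. The defaults are chosen so that the reader's
point-detection F1 sits near 0.79 and — jointly with the ~20% of counts
lost to mask degradation — its sTIL score is approximately unbiased
against the geometric truth, emulating a deployed system whose scoring
constant was calibrated against pathologists. Detection quality is
measured by greedy nearest-neighbour one-to-one matching within 6 μm
(precision/recall/F1 per class; empty-vs-empty defined as F1 = 1) and mask
IoU per tissue class.

**Response cohort.** Each slide receives a molecular subtype (HER2-positive
or TNBC, default proportions 148:55) and a Miller-Payne grade from a
latent-variable ordered logit: latent = β₀ + β_sTIL·(sTIL/10) +
β_subtype·1[TNBC] + standard logistic noise, cut at four increasing
thresholds into grades 1–5; responder = grade ≥ 4. Because the responder
event is a single cut of the latent variable, the binary outcome follows an
*exact* logistic law with slope β_sTIL — which makes parameter-recovery
simulations well-posed (the refit CI should cover the truth at its nominal
rate). Defaults: β₀ = 0, β_sTIL = 0.3 per 10 points, β_subtype = 0.2,
cutpoints (−2, −1, 0, 0.85), giving a responder rate near 45% at the
cohort's typical sTIL.

## Agreement statistics

* **Lin's CCC** uses the original biased (divide-by-n) moment estimators:
  ρc = 2·s_xy/(s_x² + s_y² + (x̄−ȳ)²). The /n-vs-/(n−1) choice matters at
  small n (0.5714 vs 0.6667 on the worked three-point example) and is
  therefore fixed and documented. The 95% CI uses the Fisher z-transform
  with Lin's asymptotic variance in its erratum-corrected form. Constant
  input vectors raise a degenerate-statistic error; perfect concordance
  returns a collapsed CI.
* **COV per case** is the across-rater sample SD (n−1) divided by the mean,
  with COV = 0 by convention when the mean is 0; single-reader slides are
  excluded with a warning.
* **Bland–Altman** limits are nonparametric: the 2.5th/97.5th percentiles
  of the paired differences under the h = (n−1)p + 1 linear-interpolation
  convention (numpy's default `linear` method); the centre line is the mean
  difference.
* **McNemar's test** on the discordant-pair counts (b, c) is exact
  two-sided binomial for b + c < 25 and chi-squared with continuity
  correction (|b−c|−1)²/(b+c) otherwise; b = c = 0 gives p = 1. The switch
  point is a package convention, documented because the source of the
  procedure does not state which variant it used.
* **t tests** (Student pooled-variance and paired) and the chi-squared test
  of independence delegate to scipy behind the module surface, with
  explicit degenerate-input errors (zero pooled variance; constant nonzero
  paired differences).

## Triage and revision

A slide is **discordant** when the maximum pairwise absolute difference
among its human scores is ≥ 10 percentage points; a (slide, rater) pair is
**revisited** when |rater − automated| ≥ 10. The boundary is inclusive by
default (a difference of exactly 10 triggers) because the workflow's
summary language ("concordant = less than 10 points") implies ≥ triggers,
while its figure caption says "more than"; the rule is configurable and
the effective setting is recorded in every report. During simulated
revision each flagged rater rescores with probability q (default 0.9) to
`round((1−w)·old + w·automated + ε)` clamped to [0, 100], with reliance
weight w (default 0.8) and optional Gaussian ε (default 0). Rounding is to
the nearest integer, not the rater's coarse visual grain, so that full
reliance (w = 1, ε = 0) reproduces the automated score exactly. The
accounting distinguishes *revisited* (returned for review) from *rescored*
(actually changed): per-rater revisit rates are over the slides that rater
evaluated, change rates over that rater's revisited slides, the unique
revisited count equals the sum over multiplicity strata (slides flagged by
exactly k raters), and before/after discordance feeds the McNemar pair
counts. An optional "distrust" response (raters moving away from a
visibly erroneous automated read) is not modelled; revision always pulls
toward the automated value.

## Response analysis

sTIL strata are low (< 10), intermediate (10–49) and high (≥ 50); Miller-
Payne grades 4–5 are responders. `response_analysis` reports responder vs
non-responder mean ± SD with Student's t, and a logistic fit of responder
status on stratum indicators with low as reference, overall and within each
subtype. The logistic fit is authored here (IRLS with Wald SEs from the
inverse observed information; convergence = max coefficient change < 1e-8;
log-likelihood tracked per iteration and non-decreasing; |coef| > 30 raises
a separation error) and is cross-checked in the tests against the 2×2
closed form (OR = ad/bc, Woolf SE) and against an independent GLM
implementation. Wald (not profile) intervals are used throughout.

## Numerical and design choices

* Determinism: every operation is a pure function of (inputs, seed); the
  pipeline spawns independent seed streams per slide from one root seed,
  and a fixed (config, seed) reproduces the report bundle byte-for-byte.
* Degenerate inputs fail loudly (undefined score, degenerate statistic,
  separation) rather than returning silent zeros; per-pair concordance
  cells with < 3 shared slides are marked unavailable instead of raising.
* The synthetic study default sizes (1.2 mm slides at 2 μm/px, 50 slides;
  200 slides and four raters in the largest validation run; 100-replicate
  property checks) are the package's desk-scale choices: large enough for
  the directional properties of the workflow to be stable, small enough to
  run on a laptop core in minutes.
* Reader studies of this design sometimes report stratum-contrast odds
  ratios on scales (≈ 1.1–1.4) that cannot be reconstructed from standard
  category contrasts; the package implements the standard
  indicator-contrast parameterization and makes no claim of numerical
  equality to any externally reported odds ratio.

## Limitations

The generator emulates geometry and error structure, not histology: no H&E
pixel synthesis, no nuclear morphology, no stain or scanner variation, no
necrosis/artifact exclusion rules, and no intratumoral-TIL scoring. Rater
error is stationary (no learning, fatigue or washout effects), and the
revision model has no distrust branch, so passing tests demonstrate the
internal consistency and directional behaviour of the scoring and revision
machinery under the stated generative assumptions — not the field
performance of any real detection model or reader panel. Cohort-level
quantities that depend on a specific real dataset and trained model (e.g.
particular CCC or COV values) are covered by directional and arithmetic
checks, not by numerical reproduction.
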