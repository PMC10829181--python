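# Methods

`timeuse` implements a complete compositional-data-analysis (CoDA)
pipeline for studying how the 24-hour balance of moderate-to-vigorous
physical activity (MVPA), light physical activity (LPA), sedentary
behaviour (SB) and sleep relates to regional grey-matter volumes and
cognition in older adults, together with a synthetic cohort generator
that reproduces the statistical structure such a study assumes.  This
note records the models, the defaults and the design decisions.

## Compositional geometry

A day's time use is a 4-part composition: only the relative split of
the fixed 1440-minute day is informative.  The package works in
Aitchison geometry throughout:

* **Closure** rescales a strictly positive vector proportionally to a
  constant `kappa` (default 1440 min).  Zero parts are rejected at the
  core level; zero handling is owned by the accelerometry stage, which
  replaces a never-observed behaviour with half the smallest observable
  increment (half an epoch, i.e. 0.5 min at 60-s epochs) and flags the
  replacement.  This keeps the mathematical core total and explicit.
* **Pivot ilr coordinates.** Coordinate i of a D-part composition is
  `sqrt((D-i)/(D-i+1)) · ln(x_i / g(x_{i+1..D}))` with `g` the geometric
  mean.  The contrast matrix has orthonormal zero-sum columns, so the
  map is an isometry from the simplex (Aitchison metric) to R^{D-1} and
  has an exact inverse.  The default regression ordering is
  (MVPA, LPA, SB, sleep) with MVPA as the first pivot; whole-composition
  inference is invariant to this ordering (tested to 1e-8 on the joint
  F statistic), so the choice is cosmetic and configurable.
* **Compositional mean**: per-part geometric mean, then closure —
  identical to inverting the arithmetic mean of ilr coordinates.
* **Symmetric balances.** For a highlighted pair (i, j), the pair of
  coordinates `z1 = α ln x_i + β ln x_j + γ Σ_rest ln x_k` and its
  i↔j mirror, with (α, β, γ) the solution of zero-sum, unit-norm and
  mutual-orthogonality constraints.  Substituting the zero-sum identity
  gives a quadratic whose discriminant is exactly 1, hence the closed
  forms `γ = −1/√(D(D−2))`, `α = (√((D−2)/D)+1)/2`, `β = α − 1`; for
  D=4 these are (2+√2)/4, −(2−√2)/4, −√2/4.  The sign convention α > 0
  makes z1 increase with part i, matching the "dominance" reading of
  the Pearson correlation between z1 and z2: positive when both parts
  rise together at the expense of the rest, negative when one rises at
  the other's expense.

Numerical tolerances: 1e-12 for pure arithmetic identities (closure
idempotence, basis Gram matrix), 1e-9 for geometry identities
(isometry, norm preservation), comfortably inside double-precision
headroom at the magnitudes involved.

## Accelerometry extraction

The pipeline starts from epoch-summarised ENMO (Euclidean norm of
acceleration minus one g, floored at zero, in mg); raw 100-Hz
processing is out of scope.  Epochs are classified in precedence order
sleep → non-wear → intensity:

1. epochs inside the logged bed-to-wake window or a logged nap are
   sleep regardless of ENMO (sleep is scored from the diary, not the
   trace);
2. epochs flagged non-wear or inside a logged removal interval are
   non-wear (no algorithmic non-wear detection — the diary is taken as
   ground truth);
3. remaining waking epochs use wrist cut points: MVPA strictly above
   93 mg, LPA strictly above 48 mg, SB otherwise.  Boundary values fall
   to the lower class by the strict inequalities; both cut points are
   configuration, since published cut points are sometimes re-scaled
   for device sampling frequency.

Epoch length is configurable with a 60-s default, which keeps day
summaries exact in whole minutes.  A valid wear day needs ≥ 600 min of
waking wear and < 360 min of non-wear (jointly implying ≥ 18 h average
wear); inclusion needs ≥ 3 valid weekdays, ≥ 1 valid weekend day
(Saturday/Sunday by the local calendar) and an average recorded daily
total ≤ 1500 min, interpreted as the mean over valid days.  Exclusions
are reported with machine-readable reasons, never raised.

Averaging behaviour minutes across days and then closing is not the
same as closing each day and averaging; the former matches the
participant-level framing used here and is what the tests pin down.

## Synthetic cohort

The generator draws, per participant: age ~ Normal(65.6, 3.0) truncated
to [60, 71.2]; female with probability 0.67; education ~ Normal(16.6,
3.2) truncated to [7, 30]; site A/B and distortion-correction use each
with probability 0.5.  Age is standardized by the truncated-normal
moments so correlation loadings land on their targets.

Compositions are logistic-normal: multivariate normal in pivot ilr
space, mapped back through the exact inverse.  The ilr mean is the ilr
image of the compositional centre (90.7, 178.8, 668.2, 502.2) min/day;
the ilr covariance is `V' diag(σ²) V` with per-part log-SDs from the
delta method (σ_k = SD_k/mean_k using part SDs 47.1, 50.7, 92.2, 57.5),
treating log-parts as independent.  This reproduces the centre exactly
in expectation and the spreads approximately (the delta method
understates the SB spread somewhat); the centre calibration is what the
tests assert (sample compositional mean within 5 min/day of the target
at n = 378).

Volumes (TIV, total grey matter, frontal, temporal, hippocampus,
lateral ventricles) are built from unit-variance latents with a fixed
correlation matrix — reported between-ROI correlations where available
(e.g. GM–temporal 0.70, GM–frontal 0.67, temporal–ventricle −0.32) and
modest assumed values (0.2–0.6) for TIV, verified positive-definite —
plus age/sex loadings equal to the target marginal correlations (e.g.
age–GM −0.28, sex–frontal +0.12).  Lateral ventricles (and the
descriptive white-matter-hyperintensity volume) are log-normal, which
is why the analysis stage log-transforms the ventricle outcome.  Small
site and distortion offsets (0.2 and −0.1 SD) are added to brain
volumes but not to the latents used for cognition, mimicking scanner
effects that the adjustment stage removes.

Cognition composites follow an explicit linear model: covariate
effects, an ilr coefficient vector, a main effect of the standardized
moderator ROI, an ilr×ROI interaction vector, and Normal residuals
(SD 0.9).  Defaults emulate the reported sign/magnitude structure: a
negative MVPA-pivot × frontal-volume interaction for long-term memory
(≈ +0.25 SD per +30 min MVPA in the lower-volume stratum, ≈ −0.05 in
the upper), a positive SB/sleep-balance × total-GM interaction for
executive function (≈ ±0.03 SD per 30-min sleep↔SB swap by stratum),
and a main MVPA effect with no interaction for processing speed.
Missingness is completely at random per composite, with rates chosen to
give expected analysed ns of 360/363/368 at n = 378.  The exact
standardized moderator used in generation is emitted as a `truth_*`
column so recovery and calibration tests can fit the generating design;
the analysis pipeline itself never uses it.

What the generator does *not* emulate: diurnal activity rhythms,
day-to-day within-person variability, non-normal cognitive score
shapes, informative missingness, and any real spatial structure in the
volumes.  Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the assumed model, not robustness to
real-data violations of it.

## Statistical stages

* **Composites**: each test z-scored over its non-missing values,
  composite = mean of available test z-scores (higher = better).
* **ROI adjustment**: residuals of volume on TIV + site + distortion,
  plus the sample mean, keeping the ml scale; adjusted volumes are
  exactly orthogonal to the adjusters in-sample.
* **Correlation table**: Pearson (point-biserial for the 0/1-coded sex,
  female = 1) with Fisher-z CIs `tanh(atanh r ± 1.96/√(n−3))`;
  within-composition pairs use the symmetric-balance correlation with a
  seeded percentile bootstrap (1000 resamples).  Deletion is
  pairwise-complete; compositional pairs require all four parts because
  the balance involves the remaining parts.
* **Regression models**: OLS with the composition entering as one
  3-column ilr term.  Model 1 = covariates (age, sex female=1,
  education in years); Model 2 adds the composition; Model 3 adds the
  squared ilr coordinates and is compared to Model 2 by a nested F-test
  (df1 = 3).  "Quadratic" means squared pivot coordinates only —
  cross-products are deliberately excluded by default since a literal
  squared-term model is the intended alternative; the term machinery
  accepts any extra columns if cross-products are wanted.
* **Type II F-tests**: for each term T the comparison model contains
  every term except higher-order relatives of T (marginality: no main
  effect is tested in the presence of its own interaction), the reduced
  model additionally drops T, and
  `F = ((RSS_reduced − RSS_comparison)/df1) / (RSS_comparison/df2)`
  with df2 the comparison model's residual df.  Multi-column terms are
  tested jointly (composition df1 = 3; composition×ROI df1 = 3
  continuous or mean-split, 9 for quartiles).
* **FDR**: Benjamini–Hochberg step-up within one model's term family,
  never pooled across models.
* **Moderation models**: covariates + composition + adjusted ROI +
  composition×ROI, with the ROI continuous, mean-split (indicator above
  the sample mean) or in quartiles.  Missing cognition is handled by
  listwise deletion per outcome model.

Model-fit diagnostics are deliberately not automated into
transformations; the one transformation the pipeline encodes is the log
of the ventricle volumes, whose generating distribution is skewed.

## Reallocation curves

From a reference composition (the analysed sample's compositional
mean), `reallocate` displaces Δ minutes towards a target behaviour
either pro-rata — remaining parts scaled by
`(κ − target_new)/(κ − target_old)` — or one-for-one from a named
donor.  Any displacement driving a part to zero or below raises (and
is dropped, with a log note, when building curve grids).  The default
grid is −60…+60 min in 15-min steps; 15 minutes is the substantively
meaningful increment and ±60 brackets the 30-min swaps usually
discussed.

The predicted cognitive difference between displaced and reference
compositions is `d'β̂` where `d` is the design-row difference — nonzero
only in the ilr and ilr×ROI columns, so covariate choices cancel — with
a delta-method CI `d'β̂ ± t_{df,0.975} √(d'V̂d)`.  This is a confidence
interval for the mean difference, not a prediction interval for an
individual.  Stratified curves fit the moderator continuously and
predict at each stratum's mean adjusted volume (above/below the sample
mean); refitting within strata is available through the categorical
`roi_form` options.  At Δ = 0 the difference and its CI are exactly
zero by construction.

## Problem sizes and seeds

All randomness flows from explicit seeds; the pipeline spawns one
substream per stage so repeated runs are byte-identical.  Calibration
suites use 500 replicates at n = 378 (the default study size): 95% CI
coverage of planted composition and interaction coefficients is
asserted within 92–98%, and the type-I error of the interaction test
within 0.05 ± 0.02 at α = 0.05.  Geometry identities use 1000 random
compositions.  The smoke pipeline tests run at n = 120 with 200
bootstrap resamples, which preserves every code path at lower cost.

## Known limitations

* Inclusion screening interprets "average daily total > 1500 min" at
  the participant level (mean over valid days), one of several
  defensible readings.
* The generator's between-ROI correlations involving TIV are
  assumptions, not published values.
* Wrist accelerometry itself cannot separate standing from sitting and
  misclassifies some stationary exercise; the package inherits whatever
  biases are present in its epoch-level inputs.
* The symmetric-balance construction is derived from its defining
  invariants; other software may differ by sign convention.
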