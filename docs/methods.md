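# Methods

This note documents the statistical machinery implemented in
`camtrapmeta`, the assumptions behind it, the defaults of the
synthetic-data generator, and the numerical and design choices that were
genuinely open.

## Data model

A *study* is one primary method-comparison study with covariates: camera
type (film/digital), attractant use, habitat openness (closed/open),
absolute latitude in degrees, the minimum body weight (grams, > 0) of the
focal species, and a three-level ordinal author recommendation ordered
`other_method < ambiguous < camera_trap` (larger latent values are more
camera-favourable; this orientation makes a film disadvantage appear as a
negative film coefficient). A *comparison* is one paired measurement
(camera value, other-method value, both nonnegative and in the same units)
under one of nine metrics with a fixed "better" direction; higher is
better for species richness, detection rate, detection probability and
individuals detected, lower is better for latency to detection, percent
bias, coefficient of variation, implementation effort and cost. The
comparison survey-method vocabulary defaults to 22 classes and is
extensible through YAML config, since class definitions vary between
evidence bases. CSVs are UTF-8, comma-separated, "."-decimal, header
required; `#` lines are metadata comments.

## Effect sizes

The log response ratio is used because the paired values arrive on wildly
different scales and mostly without variances, which rules out
variance-weighted effect-size families. Orientation puts camera traps in
the numerator for higher-better metrics and in the denominator otherwise,
so positive always favours camera traps. Zero-valued pairs are excluded
and counted rather than continuity-corrected: a log ratio is undefined
there, and an additive offset would inject an arbitrary scale into a
ratio-scale statistic. Two invariants pin the implementation down:
swapping the pair negates the effect size for every metric direction, and
rescaling both values by any positive constant leaves it unchanged.

## Stratified bootstrap

Comparisons from one study share design, site and observer, so the study
is treated as the exchangeable unit. The default *cluster* scheme per
replicate: resample the group's S distinct studies with replacement, draw
one comparison uniformly at random from each sampled study, record the
median of the S drawn values. The point estimate is the median of the
replicate medians, the 95% CI the 2.5%/97.5% replicate quantiles, the SE
the replicate SD, and a group is significant when its CI excludes zero.
An alternative *fixed-studies* scheme (study set held fixed, only the
within-study draw randomized) is available behind `scheme=`, because the
resampling unit is a genuinely open choice for this design; the cluster
scheme is the default as the standard two-stage cluster bootstrap.

Groups need strictly more than 15 comparisons (default) to be analysed;
smaller groups are reported as skipped rather than silently dropped.
Pairwise Wald tests compare group medians using bootstrap SDs as SEs at a
plain α = 0.05 with no multiplicity correction, matching the post hoc,
descriptive role of these contrasts.

Randomness: one root seed; each group's generator is derived from the
root seed plus a SHA-256 hash of the group label, so results are
reproducible bit-for-bit and adding or reordering groups never perturbs
the others.

Calibration: for groups where each study contributes one effect size the
95% quantile interval attains nominal coverage (the test suite measures
~95% over 500 simulation repetitions at 200 studies). When studies
contribute many comparisons, the two-stage draw adds within-study
variance to the replicate distribution and the interval becomes
conservative (coverage above nominal); the tests document this
one-per-study calibration and the equal-influence property (inflating a
study's comparison count with copies of its value leaves the replicate
draw unchanged exactly).

## Proportional-odds model of recommendations

P(Y ≤ j | x) = logistic(θⱼ − xβ) with J = 3 categories, two strictly
ascending thresholds and common slopes. Fitting is direct maximum
likelihood: L-BFGS-B with an analytic gradient on an unconstrained
parameterization (first threshold plus log-gaps), started
deterministically from the empirical cumulative logits with zero slopes,
followed by Newton refinement in the natural parameter space until the
gradient infinity-norm is below 1e−6 (quasi-Newton termination criteria
can stop a hair short of that on flat likelihoods). Standard errors come
from the observed information, obtained by central finite differences of
the analytic gradient. Complete separation is detected as a vanishing
gradient at divergent parameter values (|β| > 30 or |θ| > 100 on the
logit scale) and flagged as non-convergence; non-converged candidates are
dropped from the averaging set with a warning instead of failing the run.

Continuous covariates (latitude, log minimum weight) are centred and
divided by twice their population SD, which puts them on the scale of the
0/1 indicators; a standardized column has mean 0 and SD 0.5. Minimum
weight is log-transformed first because body-mass distributions are
strongly right-skewed. Scaling constants are stored for later prediction.

## Random-intercept linear mixed model of effect sizes

y_ij = x_ij′β + b_i + e_ij with b_i ~ N(0, σ²_study),
e_ij ~ N(0, σ²_resid). For a fixed variance ratio λ = σ²_study/σ²_resid
the GLS fixed effects and ML residual variance are closed-form via the
per-study Woodbury identity, so the fit reduces to a one-dimensional
search over λ: a coarse log-spaced scan over [0, 1e6] followed by bounded
Brent refinement (absolute tolerance 1e−8). ML rather than REML is used
throughout because candidate models differ in their fixed effects and are
compared by AICc. λ = 0 is a legitimate boundary solution (no study
effect) and is retained with a flag; one-comparison-per-study designs
leave λ unidentifiable and are flagged and warned about. Fixed-effect SEs
come from the GLS covariance at the ML λ (no small-sample df correction),
consistent with the normal-based 95% CIs used downstream. The
fixed-effects design joins study-level covariates (standardized at the
study level) to comparison rows and adds metric and method as whole
factor terms, dummy-coded against the alphabetically first level present.
All levels present in the data enter the saturated model; collapsing of
rare method classes is left to the caller's vocabulary config.
Collinearity is screened with VIFs (1/(1−R²) per design column, infinite
under perfect collinearity); values are reported per column and the
maximum is logged when it reaches 3. With many sparse method dummies the
max VIF can modestly exceed 3 on synthetic data; the screen is a
diagnostic, not a gate.

## Model selection and averaging

Candidates are all 2^m subsets of the fixed-effect terms (m = 5 for the
recommendation model, m = 7 for the effect-size model; multi-level
factors enter or leave whole). Each is scored by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), where k counts slopes plus the two
thresholds for the ordinal model (a two-slope model has k = 4) and
fixed-effect columns (with intercept) plus two variance components for
the mixed model; n is the number of studies for the ordinal model and the
number of effect-size rows for the mixed model. Akaike weights are
exp(−Δ/2) normalized over the candidate set, the best set is Δ < 2,
importance is the summed weight of models containing the term, and
averaging is *natural*: a coefficient is averaged only over models
containing it with weights renormalized there — avoiding shrinkage toward
zero — with the Burnham–Anderson unconditional SE
Σ wᵢ′√(seᵢ² + (θ̂ᵢ − θ̄)²) and 95% CIs at ±1.96 SE (normal multiplier; no
df statement is defensible across a 128-model set).

A known convention wrinkle: with k = {17, 16} and n = 662 the AICc gap
between two mixed models with log-likelihoods −1022.24 and −1023.95 is
1.31; analyses that count parameters or effective sample size differently
for mixed models can report 1.29 for the same pair. The package uses the
counting rule above consistently and documents rather than absorbs such
differences; the ordinal-model AICc arithmetic has no such ambiguity.

## Synthetic-data generator

Defaults describe a ~104-study evidence base: comparisons per study are
zero-truncated negative binomial (size 1.5, pre-truncation mean 5.8;
truncated mean ≈ 6.4, for ~660 comparisons in total); the metric mix is
dominated by detection rate (0.30) and species richness (0.22) so those
groups clear the >15-comparison threshold; the method mix concentrates on
live traps (0.18), sign surveys, line transects and hair traps with the
remaining mass spread over the other classes. Fieldwork year is uniform
on 1988–2016 and drives the film probability through a logistic with
midpoint 2004 and scale 2 years (film dominant before ~2000, rare after
~2008); attractants are used with probability 0.40; 30% of studies are in
open habitat; absolute latitude is a temperate/tropical mixture (55%
N(38°, 8°), else N(15°, 10°), folded into [0, 90]); minimum weight is
log-normal (median ≈ 800 g, σ_log = 1.6).

Recommendations follow a proportional-odds process with thresholds at the
cumulative logits of a 17/41/46 category mix and slopes (−1.42 film,
−0.94 attractant, −0.40 open habitat, +0.20 latitude, 0 log weight); the
indicator contributions are centred in the linear predictor so the
marginal category mix stays near its configured frequencies whatever the
slopes (centring shifts only the thresholds, so the slopes being
estimated are unchanged). Effect sizes follow the mixed model with
intercept 0.70, camera-type effect −0.55, habitat effect −0.41, metric
and method offsets of a few tenths of a log unit, σ_study = 0.40 and
σ_resid = 0.60 — jointly chosen once so the synthetic overall median
effect lands near +0.3 log units (~30–40% higher effectiveness), a
realistic magnitude for this literature. Paired values are built by
back-transforming the true log ratio around a log-normal baseline with
the orientation arranged per metric direction, so the effects module
recovers the generating ratio exactly (generation and estimation are
exact inverses, isolating estimation error). A zero-inflation probability
(default 0.02) zeroes one side of a pair to exercise the exclusion path.

What the generator does *not* emulate: correlated metric/method choices
within a study, heteroskedastic measurement error, digitization error
from figure extraction, publication bias, or geographic clustering of
covariates. Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated model, not robustness of the
scientific conclusions to those real-data features.

## Test and simulation sizes

The suite's simulation-based checks use sizes chosen for informativeness:
ordinal slope recovery from a proportional-odds process with
unit-variance covariates at n = 2000 (per-coefficient SEs ≈ 0.04–0.05,
so the 0.1 recovery band is several SEs wide); mixed-model recovery over
200 generator replicates at the default 104 × ~6 scale, scored as the
generating coefficient lying within 2 model SEs; bootstrap coverage over
500 repetitions with 200 one-comparison studies and 1000 replicates per
interval; Wald-test power over 500 repetitions of a 0.5-log-unit
two-level contrast across 60 studies. The zero-variance consistency check
uses 50 studies × 100 comparisons, where the between-study variance is
sharply identified. All stochastic tests are seeded and deterministic.

## Known limitations

- Quantile (percentile) bootstrap intervals only; no BCa or studentized
  intervals, and the interval is conservative for multi-comparison
  studies (see above).
- Single random intercept; no crossed/nested random effects, random
  slopes, or interactions among covariates.
- No variance-weighted meta-analysis (the data model carries no
  per-comparison variances), and no shrinkage ("full") model averaging.
- The observed-information SEs for the ordinal model use finite
  differences of the analytic gradient; with near-separated data they can
  be large or degenerate, which is surfaced through the convergence flag.
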