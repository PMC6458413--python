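# camtrapmeta

Comparative-effectiveness meta-analysis of **camera traps versus
alternative wildlife survey methods**, packaged as a tested, reusable
pipeline for ecologists and biostatisticians who work with
method-comparison evidence bases: one table of primary studies (equipment,
habitat, latitude, smallest focal species, and the authors' ordinal
recommendation) and one table of paired quantitative measurements (the
same effectiveness metric measured with camera traps and with one of up to
22 alternative methods, e.g. live traps, sign surveys, line transects or
eDNA).

## What it computes

**Effect sizes.** Each paired measurement yields a direction-aware log
response ratio

    ln RR = ln(X_camera / X_other)          (higher values better)
    ln RR = ln(X_other / X_camera)          (lower values better: latency,
                                             % bias, CV, effort, cost)

so a positive effect size always means camera traps performed better.
`100·(exp(ln RR) − 1)` converts an effect size to a percent difference in
effectiveness. Pairs with a zero on either side are excluded and counted
(no continuity correction).

**Uncertainty.** Because one study contributes many non-independent
comparisons, medians per metric, per method and per study-level factor are
bootstrapped with the study as the exchangeable unit: each of 10 000
replicates resamples the group's studies with replacement and draws a
single comparison per sampled study. 95% CIs come from the replicate
quantiles; a group is significant when its CI excludes zero; groups with
more than 15 comparisons are analysed, the rest are reported as skipped.
Pairs of groups are compared with Wald tests, z = (m̂₁ − m̂₂)/√(SE₁² + SE₂²),
using the bootstrap SD as the SE.

**Models.** Ordinal author recommendations (other_method < ambiguous <
camera_trap) are modelled with a proportional-odds (cumulative logit)
regression fitted by direct maximum likelihood,
P(Y ≤ j | x) = logistic(θⱼ − xβ); effect sizes with a random-intercept
linear mixed model fitted by profiled ML. Continuous covariates are
centred and scaled by twice their SD; minimum body weight is
log-transformed first. Both models go through all-subsets AICc model
selection (2⁵ = 32 and 2⁷ = 128 candidates), Akaike weights, a
ΔAICc < 2 best set, variable importance by summed weights, and natural
model averaging with Burnham–Anderson unconditional SEs.

**Synthetic data.** A generator produces study and comparison tables with
the same statistical structure and known ground truth (proportional-odds
recommendations, mixed-model log ratios, zero-inflation), so the whole
pipeline is testable end to end without any external data.

The model-fitting pieces are scikit-learn style estimators
(`TwoSDScaler`, `ProportionalOddsModel`, `RandomInterceptLMM`, and the
`AICcModelAverager` meta-estimator) and compose with sklearn tooling.

## Worked example

```sh
camtrapmeta simulate --seed 1 --out demo
camtrapmeta run-all --studies demo/studies.csv \
    --comparisons demo/comparisons.csv --out demo/run --seed 1
camtrapmeta report --dir demo/run
```

prints (abridged):

```
Studies: 104; comparisons: 648; effect sizes: 634; excluded (zero values): 14

## Overall camera-trap effectiveness
median log response ratio 0.25 [0.07, 0.43] = 29% (significant)

## Author recommendations: best proportional-odds models
model                                  parameters  log-likelihood  dAICc  weight
camera_type + attractant                        4          -94.38   0.00    0.28
camera_type + attractant + latitude             5          -93.88   1.20    0.15
camera_type + attractant + habitat              5          -94.24   1.93    0.11
```

Reading this: across 634 usable paired comparisons the bootstrapped median
log response ratio is 0.25, i.e. camera traps were ~29% more effective
than the methods they were compared with, and the 95% CI excludes zero.
The best recommendation models all contain camera type and attractant use;
the model-averaged film coefficient here is −1.66 (digital as reference),
an odds ratio of 5.3 in favour of digital cameras producing a more
camera-favourable recommendation, and studies without attractants were
2.4 times more likely to recommend camera traps. These numbers are
estimates from synthetic data whose generating values are −1.42 and −0.94
on the logit scale; `demo/truth.json` records the full ground truth.

Every output CSV carries a `# key=value` metadata header (version, seed,
config hash), and a run is byte-for-byte reproducible from its inputs and
seed.

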