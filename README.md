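# centiclock

Methylation age clocks for the oldest old, with the analyses that surround
them — built to run end to end on synthetic aging-methylome cohorts.

## The problem

DNA methylation (DNAm) age clocks regress chronological age on beta values
(methylation fractions in [0, 1]) at CpG sites. Standard clocks are trained
on mostly middle-aged cohorts and, because penalized regression shrinks
predictions toward the training mean, they systematically **underestimate
the ages of centenarians** — exactly the people whose extreme age claims a
molecular estimator could help verify. The remedy implemented here is a
*centenarian-weighted* clock: samples aged ≥ 100 years receive a training
weight of 10, which pulls the fit back toward calibration at the extreme
tail.

Because real centenarian methylomes are access-restricted, the package
ships a first-class synthetic cohort generator that emulates their
statistical structure (ages 40–115 with a ~2.6% centenarian tail, ~55%
female, multi-cohort batch offsets, CpGs with linear/saturating/null age
trajectories, age-increasing variance, mortality hazard rising ~5% per year
of age acceleration, weak biomarker correlations). Every downstream
analysis is therefore testable against planted ground truth.

## What it implements

* **Clocks** (`centiclock.clocks`) — statsmodels-style model objects:
  * `ElasticNetClock`: weighted elastic net, objective
    `(1/2)Σᵢ wᵢ(yᵢ − b₀ − xᵢᵀβ)² + λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²)` (weights
    normalized to sum 1, α = 0.5 by default), solved by cyclic coordinate
    descent with warm starts along a 100-point log-spaced λ path and λ
    chosen by weighted cross-validation; `fit()` returns a `ClockResults`
    with sparse coefficients, `summary()`, `predict()`, JSON/CSV
    serialization.
  * `NeuralNetClock`: small fully connected ReLU regressor (64, 32 hidden
    units), weighted squared loss, full-batch Adam, fixed untuned
    hyperparameters.
  * 20-fold random-split cross-validation with per-age-stratum metrics
    (n, Pearson r, median absolute error).
* **Preprocessing** (`centiclock.preprocess`) — beta computation
  `β = max(M,0)/(max(M,0)+max(U,0)+100)`, the three-group age-correlation
  CpG pre-filter (strong positive / strong negative / near-zero), iterative
  preliminary-clock outlier removal, QC PCA.
* **Age acceleration** (`centiclock.age_accel`) — residuals of DNAm age on
  age; Cox proportional-hazards mortality models (Newton on the Breslow
  partial likelihood) stratified by cohort and combined by inverse-variance
  fixed-effect meta-analysis; biweight midcorrelation (bicor) biomarker
  screens meta-analyzed on the Fisher-z scale.
* **EWAS** (`centiclock.ewas`) — per-CpG Pearson correlation with age in
  young/middle/old age groups, signed probit Z scores computed in log-p
  space, top-K selection, cross-group Z concordance, Manhattan export.
* **Enrichment** (`centiclock.enrichment`) — one-sided hypergeometric
  enrichment/depletion of age-related CpG sets across chromatin states and
  PRC1/PRC2 binding layers, with Haldane-corrected odds ratios and signed
  −log₁₀(p) heatmap matrices.
* **Trajectories** (`centiclock.trajectories`) — hand-rolled LOWESS
  (tricube local linear regression with bisquare robustifying iterations)
  for single CpGs and state-mean methylation.
* **Pipeline + CLI** (`centiclock.pipeline`, `centiclock` command) — a
  declarative YAML scenario runner (simulate → clean → prefilter → train →
  crossval → ageaccel → ewas → enrich → assoc → trajectories) with a
  hash-stamped manifest and bit-identical reruns under a fixed seed.

## Worked example

```python
from centiclock import SimConfig, simulate_cohort, ElasticNetClock
from centiclock import clocks, preprocess

beta, sheet, annotation, truth = simulate_cohort(SimConfig(seed=1))
pre = preprocess.prefilter_cpgs(beta, sheet["age"], n_pos=150, n_neg=150,
                                eps_null=0.05, n_null=100)
sub = beta.loc[pre.selected]
ages = sheet["age"].to_numpy()

w = clocks.sample_weights(ages, 10.0)          # weight 10 for ages >= 100
model = ElasticNetClock(sub, ages, weights=w, seed=0)
result = model.fit(lambda_="cv")
print(result.summary())

cv = clocks.crossvalidate_20fold(
    lambda b, s, w_: ElasticNetClock(b, s["age"].to_numpy(), weights=w_,
                                     n_lambdas=50, seed=0).fit(lambda_="cv",
                                                               cv_folds=3),
    sub, sheet, weights=w, seed=0)
print(cv.metrics)
```

Output (seed 1):

```
   stratum    n  pearson_r  mae_years
0   40plus  600   0.977174   2.382105
1   80plus  169   0.865360   2.689296
2  100plus   16   0.710314   2.697725
```

The out-of-fold clock correlates with age at r = 0.98 overall with a median
absolute error of 2.4 years, and still attains r = 0.71 within the narrow
100–115 age band — the weighted clock stays usable exactly where an
unweighted clock collapses. Training the same elastic net only on ages
40–90 and predicting the simulated centenarians gives a mean signed
residual of about −3 years (regression to the mean); the centenarian
weighting removes most of that bias.

The same flow from the shell:

```bash
centiclock run --config scenario.yaml --out out/ --seed 1
```

writes every stage's TSV/CSV artifact plus `manifest.json` with per-stage
seeds and SHA-256 artifact hashes.

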