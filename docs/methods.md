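# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the known limits of what the test suite
demonstrates.

## Weighted elastic-net clock

The clock solves

    min_{b0, β}  (1/2) Σᵢ wᵢ (yᵢ − b0 − xᵢᵀβ)²  +  λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ]

with the weights normalized to sum to one, y chronological age in years and
x the beta values of the pre-filtered CpGs. α = 0.5 by default (an even
lasso/ridge mix, the usual choice for methylation clocks). Samples aged
≥ 100 years (boundary inclusive) get weight 10, all others weight 1; by the
replication-equivalence property this is identical to entering each
centenarian ten times, and the test suite verifies that equivalence to
1e−6.

Features are standardized inside the fit with *weighted* means and SDs, so
the penalty acts on comparable scales; the constants are stored in the
serialized clock, which makes a saved model self-contained. Zero-variance
features are rejected rather than silently dropped.

Optimization is cyclic coordinate descent on the weighted Gram matrix with
warm starts along a descending λ path: 100 log-spaced values from λ_max
(the smallest λ with an all-zero solution) down to 10⁻⁴·λ_max. After every
full sweep the algorithm iterates on the active set until stable, then
confirms with another full sweep. Convergence uses the standard path-solver
criterion max_j v_j·(Δβ_j)² < tol·(null deviance) with tol = 10⁻⁷; an
absolute coefficient-change rule is not workable on near-collinear CpG
designs (the pre-filter deliberately selects CpGs that share the age
signal, so the design has large correlated blocks and the deep end of the
path converges only geometrically). Callers that need machine-precision
solutions (the λ = 0 oracle tests) pass a smaller tol explicitly. The inner
kernel is jit-compiled with numba; a pure-Python fallback with identical
arithmetic is used when numba is unavailable.

λ is chosen by weighted k-fold cross-validation (default 5 folds inside a
training set) minimizing the weighted out-of-fold squared error; ties go to
the larger, sparser λ. Solutions are checked against the elastic-net
stationarity (KKT) conditions in the tests: exactly (≤ 10⁻⁶) on
well-conditioned designs at tight tolerance, and within a few multiples of
√(tol·null deviance) on the correlated cohort designs, which is the bound
the stopping rule implies.

## Neural-network clock

A deliberately plain fully connected regressor: standardized inputs, ReLU
hidden layers of 64 and 32 units, linear output on standardized age,
weighted squared loss, full-batch Adam (learning rate 0.01) for a fixed
budget of 1500 epochs (800 in the pipeline demo). The architecture and
optimizer settings are fixed a priori and not tuned per data set — the
model leans on over-parameterized interpolation rather than hyperparameter
search, and the same settings are used everywhere to avoid optimistic
selection. Training is deterministic given the seed (seeded He
initialization, no minibatching). With zero hidden layers the trainer
reduces to linear regression and is tested against the least-squares
solution.

## Training design and evaluation

Clocks are trained on samples aged ≥ 40 ("40+") or ≥ 100 ("100+"), both
with centenarian weight 10. Evaluation is random-split 20-fold
cross-validation: every sample sits in exactly one fold (sizes differing by
at most one), and its out-of-fold prediction comes from a model that never
saw its fold. Folds are simple random rather than age-stratified. Metrics
are reported per age stratum (40+, 80+, 100+): n, Pearson r, and the
median absolute error in years.

Age acceleration is the raw residual of DNAm age regressed (OLS, with
intercept) on chronological age; orthogonality to age then holds by
construction and is asserted to 10⁻¹⁰ throughout.

## Survival and association models

Mortality is modeled with Cox proportional hazards maximized by
Newton-Raphson on the partial likelihood with **Breslow** handling of tied
event times (the simplest standard choice; the simulator produces
continuous times, so ties are rare). Step-halving keeps the likelihood
monotone; convergence requires gradient norm < 10⁻⁸. A fitted log-HR above
10 in magnitude triggers a monotone-likelihood (perfect separation)
warning, since with separation the gradient vanishes only as the
coefficient diverges. Constant covariates get coefficient 0 with undefined
SE rather than an error. Fits are stratified by cohort and combined by
inverse-variance fixed-effect meta-analysis (weights 1/SE², combined
SE = 1/√Σw). The follow-up clock is the timescale; age enters as a
covariate alongside sex.

Biomarker screens use the biweight midcorrelation with the conventional
tuning constant 9 (observations more than 9 MADs from the median receive
zero weight); a zero MAD falls back to Pearson with a logged warning.
Per-stratum bicors are Fisher-z transformed (SE 1/√(n−3)), meta-combined as
above, and back-transformed; strata with fewer than 4 complete observations
are skipped with a log entry. The variance-stabilizing z scale is the
standard construction for inverse-variance weighting of correlations.

## EWAS

Within each age group — young [0, 40), middle [40, 90), old [90, 115],
lower bounds inclusive and the final upper bound inclusive — every CpG is
Pearson-correlated with age; p is two-sided from t = r√((n−2)/(1−r²)), and
the plotted Z score is the signed probit of the p value, z =
sign(r)·Φ⁻¹(1 − p/2). All p handling is in log space: at large n the p
values of strong CpGs underflow doubles by hundreds of orders of magnitude,
so −log₁₀(p) is the canonical representation and the linear-scale p is
floored at 10⁻³²⁰ for display. Constant or low-n CpGs are reported as
missing, never dropped silently. Cross-group concordance is the Pearson
correlation of the Z vectors over shared CpGs. Genome-wide significance in
the Manhattan export is p strictly below 10⁻⁷. The EWAS deliberately
ignores batch covariates — technical confounding biases toward the null and
is dominated by the age signal, which the batch-offset simulations confirm.

## Chromatin-state and PRC enrichment

Each CpG carries one chromatin state; PRC1/PRC2 binding are additional
non-exclusive layers defined by "at least two complex members bound"
(RING1/RNF2/BMI1 for PRC1; EED/SUZ12/EZH2 for PRC2). A query set (e.g. the
top-K positively age-correlated CpGs) is tested against an explicit
background with one-sided hypergeometric tails computed by logsumexp over
the exact log pmf — enrichment p = P(X ≥ k), depletion p = P(X ≤ k), both
including the observed point mass. The odds ratio is the sample 2×2 odds
ratio with the Haldane–Anscombe +0.5 correction (flagged) on zero cells.
Heatmap cells carry −log₁₀(min tail p) signed by OR ≷ 1, with an optional
row filter on minimum p. Tails agree with exhaustive enumeration to better
than 10⁻¹⁴ relative for all configurations with N ≤ 30.

## LOWESS trajectories

The smoother is Cleveland's LOWESS: for each point, a weighted linear fit
over the int(frac·n) nearest neighbors with tricube distance weights,
followed by robustifying iterations that reweight by the bisquare of
residuals scaled by 6·median|residual|. Defaults are the classical
span 2/3 and 3 robust iterations. The fit is evaluated at the distinct
observed ages (duplicated x values are collapsed to their mean y first),
matching scatter-plot overlay use. On exactly linear data the smoother
reproduces the line to 10⁻⁸; on a 20-point sine fixture it matches the
statsmodels reference implementation to ~10⁻¹⁵. Reported r/p per trajectory
are computed on the raw values, not the smoothed curve.

## Synthetic cohorts: what they emulate, and what they do not

The generator's defaults encode the study conditions the package targets:
600 samples × 2000 CpGs at desk scale; ages from a uniform(40, 95) body
mixed with a shifted-exponential 100+ tail (scale 5.6 years, truncated at
115) at weight 184/7039 ≈ 2.6%, matching a pooled training cohort's thin
extreme tail and its ~105.6-year centenarian mean; 54.5% female; three
source cohorts with per-(cohort, CpG) offsets ~ N(0, 0.01) on the beta
scale, weak enough that age dominates, as a QC PCA confirms (sex, planted
as a 3% block of sex-offset CpGs, separates on the leading components;
batch does not).

CpG classes: 10% positive-linear, 10% negative-linear, 5% saturating
(linear until a plateau age drawn uniform in 55–75, flat after), the rest
null; per-year slopes drawn uniform in 0.001–0.003, baselines placed so the
mean trajectory stays inside [0, 1]. Noise is truncated-Gaussian on the
beta scale with SD 0.04 + 0.0004·age — the simplest model with the
age-increasing variability the oldest-old data show; a logit-normal
alternative was considered out of scope. A latent per-sample age
acceleration ~ N(0, 3 yr) shifts every causal CpG through an effective age
(age + accel), drives an exponential mortality hazard 0.02·1.05^accel per
year (administratively censored at 15 years), and generates biomarkers with
prescribed correlations (alternating signs across the configured magnitude
range, defaults −0.17, +0.105, −0.04). Positive-linear CpGs are placed in
the bivalent/PRC-like states (BivProm1/2, ReprPC1) at odds 5, with PRC
member binding probabilities elevated there, so state enrichment is
recoverable by construction.

What passing tests therefore show: the estimators recover what was planted
at realistic effect sizes and sample sizes, the weighting mechanism
mitigates regression-to-the-mean bias under honest out-of-fold evaluation,
and every pipeline stage is deterministic and self-consistent. What they do
not show: performance on real arrays — the generator has no probe
chemistry, CpG-island structure, cell-composition drift, pedigree
correlation, or realistic genome coordinates, and the reported accuracy on
synthetic cohorts (out-of-fold r ≈ 0.98 overall, ≈ 0.7 in the 100–115
band) cannot be read as accuracy on human data.

## Problem sizes and other fixed choices

The demo scenario and the acceptance computations use 600 × 2000 cohorts
with a 150/150/100 pre-filter, a 50-value λ grid in cross-validation, 800
NN epochs, and 20 seeds for the Monte-Carlo recovery rates — sizes chosen
so the full suite exercises every claim in a few minutes while keeping the
Monte-Carlo margins comfortable. The outlier-removal rule (drop samples
whose preliminary-clock residual exceeds 30 years, at most 3 rounds) is a
deliberately blunt instrument aimed at labeling/platemap errors; it removes
nothing on clean cohorts and exactly the corrupted sample in planted tests.
Pre-filter set sizes and the near-zero band (|r| ≤ 0.02 at full scale) are
configuration, since only the three-group design, not its thresholds, is
canonical. The age-group boundaries assign 40 to "middle" and 90 to "old"
(lower-inclusive); 100.0 years exactly is a centenarian. The probit Z
(rather than Fisher's √(n−3)·atanh r) was chosen for the EWAS because it is
the construction used by the standard screening implementations this module
mirrors.

## Known limitations

* The Breslow tie correction degrades with heavily discretized event
  times; Efron weighting is not implemented.
* The elastic-net path can still be slow if given thousands of
  near-duplicate features at tight tolerance; the pre-filter sizes keep
  designs in the regime where the solver is fast.
* The NN clock overfits small cohorts by design (no early stopping); its
  cross-validated metrics are the honest numbers.
* The bicor meta-analysis does not model within-stratum dependence
  (e.g. family structure).
* PRC annotations are simulated indicator layers, not ChIP-seq derived;
  enrichment analyses demonstrate recoverability, not biology.
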