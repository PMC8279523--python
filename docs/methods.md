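# Methods

## The problem

DNA-methylation aging clocks predict chronological age from the
methylation fraction (beta value, in [0, 1]) measured at a panel of CpG
sites on Illumina 450K/27K arrays. Two model families are implemented:

1. **Linear clocks** in the Horvath protocol: an elastic-net regression on
   beta values against a log-linear transform of age.
2. **A deep clock**: a feed-forward network regressing raw age in years
   with MAE loss, preceded by a gradient-saliency feature-selection stage.

Both are exercised end-to-end on a synthetic cohort generator, so the full
pipeline is testable without any array data.

## The age transform

Linear clocks regress the transformed age
F(a) = log((a+1)/(A+1)) for a ≤ A, and (a−A)/(A+1) for a > A, with adult
age A = 20 years. The inverse used to report predictions in years is

    age = 21·exp(p) − 1   if p ≤ 0
    age = 21·p + 20       if p > 0.

The branch conditions are the only reading that makes the map continuous
and total: both branches give exactly 20 years at p = 0. The transform
compresses pediatric ages logarithmically (methylation change is fastest
during development) and is linear in adulthood.

## Linear clock fitting

`fit_elastic_net` fits scikit-learn's `ElasticNetCV` at a fixed L1/L2 mix
(`penalty_mix`, default 0.5) with the penalty strength chosen by internal
10-fold cross-validation minimizing squared error in transformed-age
space. Inputs are z-scored before fitting and the weights are mapped back
to the beta scale afterwards. Standardization is deliberate: it is what
glmnet — the engine behind the original protocol — does by default, and it
is what activates the elastic net's grouping effect, which distributes
weight across correlated age-informative CpGs instead of picking an
arbitrary sparse subset. A `standardize=False` mode fits raw betas.
Probes with exactly zero weight are dropped from the returned clock.

## Deep clock

The regressor is a fully-connected network (input → H hidden layers of W
units → 1 linear output) with ELU/ReLU/SELU activations, inverted dropout
on each hidden layer, L2 weight decay, and MAE loss minimized by the Adam
family (Adam, AMSGrad, Nadam). The engine is written in numpy with exact
backpropagation; it is seeded end-to-end, so a fixed seed reproduces a
run bit-for-bit on the same platform (cross-platform bit-identity is not
promised — BLAS summation order varies).

The defaults reproduce the reference configuration: 4 hidden layers × 512
units, ELU, Adam at learning rate 1e-4, 30% dropout, L2 1e-3, MAE loss,
fivefold cross-validation.

**Training.** Epoch budget 300 with early stopping: a 10% seeded holdout
is monitored, training stops after 20 epochs without improvement, and the
best-validation parameters are restored. Batch size 64. Weight init is
He-style (LeCun-style for SELU); biases start at zero. The two-stage
pipeline driver (`fit_deep_clock`) budgets 150 epochs per fit — early
stopping usually ends well before either limit — and screens grid
candidates at 60.

**Feature selection.** Stage 1 scores the full probe panel by gradient
saliency. Each probe's importance is the 95th percentile — linear
interpolation between order statistics, numpy's default — of the absolute
gradient of the output with respect to that input across samples,
computed with dropout disabled. The percentile is taken per feature
across samples: that is the only reading that ranks features. The score
is averaged over a small ensemble (default 3) of independently seeded
networks trained with input dropout 0.5 and L2 1e-2 on top of the
reference architecture. Both additions target the same failure mode:
age-informative CpGs are highly redundant, so a single unconstrained fit
uses only a subset of them and memorizes noise probes with the rest of
its capacity, corrupting the ranking. Input dropout forces every fit to
spread usage across correlated probes; averaging across seeds cancels
the saliency noise probes acquire in any one fit. The top-k probes
(k = 1000 at full scale) are then fixed, sorted by descending importance
with ties broken by ascending probe ID. The input dropout and extra L2
apply to the saliency stage only; grid candidates and the final model
train without them.

**Grid search.** Stage 2 searches depth {2,3,4,5}, width
{128,256,512,1024}, activation {ELU,ReLU,SELU}, optimizer
{Adam,AMSGrad,Nadam}, learning rate {1e-3,1e-4}, dropout {0.15,0.3,0.5},
L2 {1e-6,1e-4,1e-3,1e-2,1e-1}. The full product is large, so a `budget`
draws a seeded uniform subsample of configurations. Each candidate is
scored by k-fold cross-validated mean MAE with folds that are seeded and
age-decile-stratified. Candidates are screened at a reduced epoch budget
(`grid_search_epochs`, default 60) — a standard screening economy; the
winner is then used at the full budget for the out-of-fold predictions and
the final all-sample model.

**Targets and input representation.** The network regresses raw age in
years (the output is "a continuous age value"); a transformed-target mode
is not needed because MAE in years is the reported metric. Inputs are
beta fractions **mean-centered per probe**: the per-probe training means
are stored with the model and subtracted at inference. Centering is
load-bearing, not cosmetic — beta values sit on large per-probe baselines
(0.1–0.9) while the age signal moves them by ~0.01–0.05, and feeding the
raw offsets through the first layer leaves the optimizer in a long
plateau at the mean predictor that the early-stopping window aborts.
Centering removes the plateau while keeping the inputs on the beta scale;
the variance is deliberately not rescaled (no z-scoring), so probes with
larger age-driven variation still carry proportionally larger signal.

## Evaluation battery

* Metrics: MedAE, MAE, RMSE, R², Pearson's r (scikit-learn / scipy).
  Pearson's r is reported as undefined for n = 1 or zero-variance
  predictions.
* Case/control comparison: two-sided Mann-Whitney U on signed errors
  (predicted − true; positive = predicted older). Exact enumeration of
  the permutation null when both cohorts have ≤ 8 samples, tie-corrected
  normal approximation above. A seeded label permutation repeated
  `n_permutations` times (median p reported) is the negative control;
  with `n_permutations=1` the control p-value is uniform under the null,
  which is what the calibration checks use — the median of several
  permutations is deliberately conservative and serves as a stable
  "should-be-null" indicator, not as a calibrated test.
* Sex-stratified errors in half-open age brackets (20,45], (45,55],
  (55,65], (65,75], with a male-vs-female MW test per bracket.
* BMI effect: OLS of z(prediction) ~ z(age) + male + z(BMI).
* Panel overlap: exact intersection cardinalities of two CpG sets.

## Synthetic cohort generator

The generator emulates a pooled multi-study blood-methylation collection:

* **Ages** uniform over `age_range` (default 20–75 years). Real pooled
  collections are unimodal; uniform coverage is chosen so every age
  decile is testable.
* **Baselines** b0 for background probes are bimodal (normal peaks at
  0.10 and 0.85, sd 0.05) mimicking the hypo/hyper-methylated peaks of
  real beta distributions. Informative probes draw b0 uniformly in
  0.25–0.60 so the configured drift is not destroyed by clipping to
  [0, 1].
* **Linear probes**: beta = b0 + s·(bio_age − mid)/50; effect s has
  random sign and magnitude U(0.5, 1.5)·`age_effect_scale` (default
  0.15 per 50 years).
* **Saturating probes**: beta = b0 + s·(1 − exp(−bio_age/τ)), τ ~
  U(10, 30) years — a family whose slope decays with age, so a nonlinear
  model has something a linear model cannot represent.
* **Biological age** driving the probes is chronological age +
  `case_acceleration_years` for case samples + `bmi_effect_years_per_sd`
  per BMI standard deviation.
* **Study structure**: samples are assigned to `n_studies` studies;
  each study adds a per-probe offset ~ N(0, `study_offset_sd`).
* **Recorded ages**: a `round(fraction·N)` seeded subset (default
  fraction 0.17, the rate seen in real GEO metadata) is floored to whole
  years and flagged; `apply_age_censoring_correction` later adds 0.5
  years to flagged samples, undoing the expected half-year understatement.
* Gaussian probe noise (`beta_noise_sd`) is added last; everything is
  clipped to [0, 1].

What it does **not** simulate: IDAT intensities, Infinium I/II probe
chemistry, cell-composition heterogeneity, age-dependent missingness.
Passing tests therefore demonstrate pipeline correctness and statistical
behavior under the generator's assumptions, not clinical accuracy on real
arrays.

## Problem sizes used in the test battery

The bundled property battery runs at desk scale, chosen to exercise the
full protocol on one CPU: linear-clock recovery on n=400 × p=1000 with 30
causal probes (noise-free); the deep pipeline on n=600 × p=2000 with 40
linear + 20 saturating probes and beta noise equivalent to 3 years
(beta_noise_sd = 3·0.15/50), selecting k=100 features and screening a
seeded budget of 6 configurations from a bounded grid (depth ≤ 4, width
≤ 512 — the full product stays available as `DEFAULT_GRID`); power
simulations sized to 139/140 case/control with a +2.1-year implanted
shift; BMI recovery at n=94 with a standardized coefficient of 0.2.

The deep-vs-linear head-to-head runs on a **saturating-only** cohort
(n=400 × p=500, 40 saturating probes, same noise): when informative CpGs
drift linearly, the elastic net is the true model and no nonlinear
learner can beat it, so the directional claim is only meaningful — and is
tested — where the age-beta relationship lies outside the linear family.
Both families are scored by out-of-fold MedAE on shared seeded stratified
folds; the network uses the faster-learning grid point (learning rate
1e-3) at the full epoch budget, the elastic net refits its penalty inside
every training fold.

## Numerical choices and degenerate inputs

* Percentiles: numpy linear interpolation.
* Feature-selection ties: ascending probe ID (deterministic).
* Constant age targets raise a degenerate-target error; zero-variance
  training targets in the network warn but proceed.
* The elastic net raising every coefficient to zero is surfaced as a
  degenerate-target error rather than returning an empty clock.
* Beta values outside [0, 1] are rejected at the IO boundary with the
  offending probe/sample named.
* Missing betas: harmonization fills per-probe reference medians when
  supplied, otherwise 0.5 under the `constant` policy; `error` refuses.

## Known limitations

* The numpy network trains on one CPU; it is sized for thousands of
  probes, not the full 450K array.
* Determinism is per-platform; different BLAS builds may differ in the
  last float digits.
* The generator's uniform age distribution and independent probe noise
  understate the correlation structure of real arrays; feature-recovery
  rates on real data will be lower.
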