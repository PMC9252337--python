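# Methods

## The prediction task

Each subject is followed over irregularly spaced clinical visits. At visit
t the model sees the subject's clinical history x(1..t) — scale values,
current ICD status, treatment flags, derived dopamine-agonist (DA)
exposure, time-to-next-visit and follow-up length per visit — together with
a static vector s (age at baseline, sex, SNP dosages), and predicts the
probability of an ICD at visit t+1. A subject with n visits contributes
n−1 observations; observations of one subject are never split across a
train/evaluation boundary.

## Synthetic cohort generator

Real PD cohorts of this kind are access-restricted, so the generator
produces cohorts with the statistical structure the analysis assumes, with
known coefficients so that recovery is testable.

**Visit process.** The number of visits per subject is a rounded Gaussian
clipped to [2, 15] (default mean 7.18, sd 2.96 for the drug-naive dialect;
5.41 / 1.66 for the treated dialect); intervals are Gaussian (0.95 ± 0.35
vs 1.09 ± 0.33 years) truncated below at 0.25 years. The first visit is at
time 0. There is no informative dropout or death process.

**Clinical scales.** Each scale (anxiety, depression, REM sleep, motor
exam) evolves as a Gaussian AR(1) around a subject-level mean, with the
total variance split 40% between subjects and 60% within, and
autocorrelation ρ = 0.7. This produces the visit-to-visit continuity that
forward-fill imputation presumes. The two dialects use different scale
locations (e.g. STAI-like anxiety 93.6 ± 8.0 vs HAD-like 6.8 ± 3.8),
emulating cohorts assessed with different instruments; the REM indicator is
generated as a continuous scale in both dialects and harmonized purely by
standardization.

**Genotypes.** Each of 31 biallelic SNPs gets a minor allele frequency
drawn uniformly from (0.05, 0.5); dosages are Binomial(2, MAF), i.e.
Hardy–Weinberg by construction. Genotype QC is out of scope — synthetic
dosages are generated clean. Per-SNP outcome effects default to zero
(candidate-gene effects on ICDs are weak and inconsistently replicated);
they are configurable for power studies.

**Treatment.** DA episodes start at a visit with probability 0.18 per
visit (geometric over visits), carry a daily dose drawn uniformly from
50–300 LEDD, stay constant between visits, and stop with probability 0.05
per visit. The drug-naive dialect forbids any exposure at time 0; the
treated dialect starts 35% of subjects on a DA (55% on levodopa) at
baseline. Levodopa and "other" medication are tracked as binary flags.

**Outcome model.** ICD status is generated sequentially by a first-order
Markov logistic hazard: the status at visit t+1 is Bernoulli with logit
β₀ + β_prev·y(t) + Σ βⱼ zⱼ(t+1) + γᵀ(g − ḡ), where the zⱼ are the scale
values standardized by their configured population moments, age
standardized at (60, 10), sex centered at the configured male fraction,
cumulative DA duration scaled by 2 years and total DA dose by 400
LEDD·years. Covariates enter at the visit being generated ("current" at
t+1); the baseline status uses the same covariates without the persistence
term around a configured baseline prevalence. Default effect directions
follow the known clinical risk factors: male sex, prior ICD, depression,
REM disturbance, motor severity and cumulative DA duration increase risk;
older age, anxiety and (weakly) total DA dose decrease it.

**Calibration of the defaults.** β₀ = −2.85 (drug-naive) and −2.3
(treated) were set from the Markov chain's stationary prevalence together
with the DA-exposure drift so that default cohorts land at ≈14% and ≈27%
observation-level prevalence and ≈13% / ≈20% baseline prevalence — the
regime in which the persistence baseline is strong but beatable. These are
generator constants, not tuned per run.

**Missingness** is MCAR at 5% per scale by default (a mechanism choice:
nothing in the emulated setting characterizes the missingness process).
ICD status, sex, age and medication are never masked, and at least one
baseline value per scale is retained cohort-wide so the training baseline
mean always exists.

## Preprocessing

Missing scale values are imputed by forward fill (most recent non-missing
value of the same subject and feature); remaining baseline missing values
get the mean baseline value of the *training* subjects. Features are then
z-scored with training-set moments (population sd); binary indicators and
SNP dosages are standardized like continuous features — "each feature" is
taken literally, and it is harmless for the downstream linear and neural
models. Zero-variance features are centered and scaled by 1 with a warning.
The standardizer records a fingerprint of the subject ids it was fitted on,
and the harness asserts disjointness from every evaluation set; the same
training statistics are applied to the replication cohort, mirroring the
application of a model trained on one cohort to another measured with
different instruments.

Derived DA features at time t are computed from exposure intervals
intersected with [0, t]: cumulative duration (years), total dose
(LEDD·years — years keep the two magnitudes commensurate), maximum daily
dose, and mean daily dose = total/duration. "Follow-up length" at visit t
is its time since baseline; "time to prediction" is the interval from visit
t to visit t+1, a scheduling quantity known in advance.

## Models

**Trivial persistence baseline** — predicts the status at the most recent
visit, as both class and score. Because its scores are binary, its ROC AUC
equals its balanced accuracy identically; this shows up as an invariant in
every report.

**Reduced-history logistic regression** — the history is collapsed by a
convex combination w ≥ 0, Σw = 1 over visits (baseline-only, last-only,
uniform over all past visits including the current one, or
exponential-recency w_i ∝ α^(t−i), the configurable realization of
"higher weights to more recent visits"); the summary visit is concatenated
with the static features and fit with an ℓ1 or ℓ2 penalty of strength λ
(intercept unpenalized; lbfgs for ℓ2, saga for ℓ1). The λ grid is
logarithmic, 10⁻³…10³, 13 points.

**GRU-static fusion** — a single-layer gated recurrent unit (standard
update/reset-gate equations) reads the clinical sequence into h(t); h(t)
is concatenated with s and mapped through one fully connected layer and a
sigmoid. All treatment and dose features travel in the sequential branch
(configurable in principle; the clinical/static split keeps
time-independent socio-demographic and genetic data out of the recurrence).
The network is trained end-to-end with Adam on binary cross-entropy — h(t)
is never estimated separately. Implemented directly in NumPy (forward,
backprop-through-time, Adam with decoupled weight decay); gradients are
verified against finite differences, and batched padded evaluation is
verified to be exactly equal to per-sequence evaluation (hidden state is
carried unchanged through padded steps).

Defaults: hidden size 16, learning rate 10⁻², batch 64, ≤200 epochs with
early stopping (patience 20) on the ROC AUC of an internal 15% subject-level
validation split, decoupled weight decay 3.0 on non-bias parameters. The
strong decay is the network's counterpart of the logistic ridge penalty: at
a few hundred subjects the dominant failure mode is overfitting through the
static branch (31 SNP dosage inputs), and with lr·decay = 0.03 per step the
effective shrinkage matches what early stopping alone cannot provide. Class
weighting is off by default (threshold-0.5 operating points are reported
for unweighted training); a positive-class weight is available in the
config.

## Evaluation

Metrics: midrank ROC AUC (exactly P(score⁺ > score⁻) + ½P(tie), checked
against exhaustive pair counting), average precision (recall-increment
weighted precision, no interpolation; equals prevalence for an
uninformative scorer), and accuracy / balanced accuracy / sensitivity /
specificity at the strict score > 0.5 convention.

The DeLong test estimates the covariance of two correlated AUCs from
placement values (structural components) computed with midranks in
O(n log n); per-model 95% CIs use each AUC's own asymptotic normal
distribution. Degenerate comparisons (zero variance of the difference,
e.g. identical scores) return difference 0 and p = 1, flagged. P-values
across all model-vs-baseline comparisons are Bonferroni adjusted,
p ↦ min(1, m·p). The implementation agrees with pROC's DeLong test to
6 decimals and its type-I error is nominal under a correlated null (both
in the test suite). Treating repeated visits of one subject as independent
understates DeLong p-values; a subject-level cluster bootstrap of the AUC
difference is provided as an optional sensitivity analysis.

**Nested cross-validation.** The training cohort is split 80/20 at the
subject level (floor convention on the test count), stratified by
ever-having-an-ICD so prevalence stays comparable — the split rule itself
is a design choice where plain random splitting would also do. Inner
5-fold subject-level cross-validation over the hyperparameter grid selects
by mean inner ROC AUC, with ties broken toward smaller λ and then grid
order; each inner fold recomputes imputation means and standardization
moments from its own training subjects. The selected model is refit on the
full outer-training set and evaluated on the outer-test subjects and on the
entire replication cohort. DeLong comparisons on the training cohort use
the outer-test subset. The roles of the cohorts can be swapped by
exchanging the arguments, and the outer split can be repeated R times. A
clinical-only ablation (`--feature-set clinical_only`) drops the SNP
columns without separate code.

## What the tests show — and what they do not

The generator's defaults put the pipeline in the regime the emulated
setting reports: strong visit-to-visit persistence, ~14%/27% prevalence,
exposure-driven excess risk. The acceptance experiment uses two 300-subject
cohort pairs (chosen so the whole comparison runs in seconds on one CPU):
with β_dur dominant, the GRU fusion model beats the trivial baseline on
both cohorts with Bonferroni-adjusted DeLong p ≤ 0.05; with pure
persistence, the difference is statistically and practically null. Passing
these tests shows the machinery is sound — leak-free, calibrated,
able to recover planted signal. It does *not* show that real PD cohorts
contain that signal: the generator's MCAR missingness, Gaussian AR(1)
scales, piecewise-constant dosing and first-order Markov outcome are
idealizations, and real instruments, dropout and diagnostic noise can only
reduce attainable performance.

## Numerical and degenerate-input conventions

- Population (ddof 0) standard deviations in the standardizer; zero
  variance ⇒ scale 1 with a warning.
- Single-class evaluation sets raise an undefined-metric error rather than
  returning a value.
- A degenerate internal GRU validation split (one class) scores 0.5 so
  training proceeds without an early-stopping signal rather than crashing.
- Subjects with fewer than two visits are rejected at construction
  (inclusion criterion).
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; identical config ⇒ byte-identical cohorts and identical fits.
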