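# Methods

This note documents the models, conventions and numerical choices behind
the package: what the synthetic cohort generator assumes, how each analysis
stage is defined, which decisions were genuinely open, and what passing the
test suite does and does not establish about real data.

## The latent-trait cohort model

Every simulated measure derives from a single-common-factor model. Each
participant carries a latent attention-speed trait θ ~ N(0, 1) (higher =
slower attentional engagement). Measures are monotone links of
`z = λ·θ + √(1−λ²)·ε` with measure-specific standard-normal noise ε, so the
cross-measure correlation structure is controlled entirely by the loadings
λ.

**Intrusion propensity.** `p_intrusion = logistic(a + b·θ)`. The intercept
and slope are solved by two-dimensional moment matching (Gauss–Hermite
quadrature + root finding) so the population mean and SD of the propensity
equal the configured targets (defaults .296 and .200, the values a large
adult cohort shows). A requested SD with `sd² ≥ mean·(1−mean)` cannot live
on (0, 1) and raises a configuration error. The guess propensity is an
independent Beta-distributed fraction (mean .115, concentration 50) of the
non-intrusion mass, so `p_correct + p_intrusion + p_other = 1` holds by
construction and the population guess rate is ≈ 8% — consistent with
single-target accuracy ≈ 62% alongside intrusions ≈ 30%. The .115/50 pair
is a package choice; only its product with the non-intrusion mass is
observable.

**Loadings.** For measures that are affine in z (RT, reading), the loading
is `λ = target / corr(p_intrusion, θ)` with the propensity–trait
correlation computed by quadrature. For nonlinear links (logit-normal
accuracies, the log-normal time-error link), λ is solved numerically on a
2-D Gauss–Hermite grid so the *population* product-moment correlation with
the propensity hits the target exactly despite the nonlinearity. Default
targets: T1 accuracy −.68, time error +.40, overall RT +.25, AB-related
accuracies and reading 0 (reproducing the null associations of the real
cohorts). Infeasible targets (beyond the maximum correlation the links
admit) raise rather than silently clamp.

**Per-measure distributions.**

- T1 / T2 accuracies: logit-normal, moment-matched to means (SDs) .829
  (.148), .811 (.177) at lag 7 and .408 (.200) at lag 3, making the
  expected AB magnitude .403.
- Time errors: the between-participant mean error uses a standardized
  shifted log-normal link (skew parameter σ = 0.6), matching a positively
  skewed distribution with mean 22.41° and SD 15.14°. Trial errors add
  within-participant noise (SD 40°, same skew family) plus a 2% mixture of
  wild responses uniform on the circle, which exercises the ±160° filter
  (discarding roughly 1–2% of trials, as real data show). The 40° within-SD
  is a package choice: it puts the split-half reliability of 100-trial mean
  time errors in the low-.9s, bracketing the ≈ .83 reported for the real
  task, while keeping the filter's tail contribution realistic.
- RTs: trial RT = participant task mean + condition offset + standardized
  shifted log-normal noise (SD 100 ms, σ = 0.6; bounded below, so RTs stay
  positive). Search-task means are N(547, 58²) with an age slope giving
  corr(age, RT) ≈ .36 (age ~ N(27, 6²) truncated to 18–45, independent of
  θ — which is why partialing age slightly *raises* the DI–RT correlation,
  as observed). Simon-task means are an affine rescaling to N(436, 52²).
  Cueing offsets (+37 different-location, −36 same-location, cue present
  80%) and the Simon offset (+81 ms incompatible, 25% frequency) are
  centered so the configured task mean is the overall mean. Accuracy is
  Bernoulli per condition (e.g., .857 incompatible vs .989 compatible).
- Sessions share the latent propensity (perfect trait stability), so
  between-session correlations of observed rates are governed purely by the
  attenuation identity `ρ ≈ σ_B² / (σ_B² + E[p(1−p)]/t)`; at t = 60 this
  predicts ≈ .93, inside the .85–.95 band the tests assert and consistent
  with the ≈ .90 stability real cohorts show.

An optional mechanistic variant draws a per-trial engagement latency
L ~ LogNormal with θ-dependent median and classifies L ≤ τ₁ → correct,
τ₁ < L ≤ τ₂ → intrusion, else guess, with thresholds at one and two
100-ms frame durations. It mirrors the diachronic account of intrusions
qualitatively and is deliberately not the default: no published equations
constrain its parameters, so it is exposed for exploration only.

**What the generator does not emulate.** No serial structure (fatigue,
practice, streaks), no stimulus-level variation (digit confusability,
stream position), no session-selective attrition, no trait drift across a
year, and no stream-count differences between task variants. Passing tests
therefore demonstrates the *pipeline's* correctness and the internal
consistency of the reliability/association machinery under the calibrated
population model — not that real data meet the model's assumptions.

## Scoring conventions

Filter boundaries follow a literal reading, applied consistently: RT trials
survive the absolute window iff `150 ≤ RT ≤ 1000` ms (strict exclusion
outside); guess rates flag a participant iff strictly over .25; participant
outliers flag iff `|x − mean| > 3·SD` (strictly), with mean and SD over the
full sample *including* the candidate. Exclusion order is trial-level
filters (correctness → window → per-participant per-condition 3-SD trim,
single pass) before any participant-level statistic. The 3-SD trim is
intentionally not iterated to a fixed point; reapplying the cleaner can
therefore trim a further sliver (the tests pin exact idempotence of the
correctness/window stages and ≥ 99% stability of the trim). Participant
flags are per-measure: a flagged participant is excluded only from analyses
involving that measure.

T2 accuracy is computed over all two-target trials of each lag,
unconditional on T1 correctness; `ab_scores(..., condition_on_t1=True)`
provides the conditional variant some AB traditions prefer. A lag with no
usable trials leaves the AB undefined (flagged), never zero.

## Time-judgment pipeline

Angles wrap to (−180°, 180°] with +180° as the boundary representative —
a unique representative makes the inclusive ±160° discard well defined at
exactly 180°. The discard is inclusive (|e| ≥ 160°), since at 180° a
+500 ms and a −500 ms latency are indistinguishable. After the discard and
the single-pass per-participant 3-SD trim, the participant score is the
*arithmetic* mean of the wrapped signed errors, not the circular mean: once
±160° errors are removed, wrap ambiguity is negligible and the arithmetic
mean matches how the measure is reported. Conversion is linear
(1° = 1000/360 ms), so mean-then-convert equals convert-then-mean;
milliseconds are rounded only for display.

## Reliability machinery

Split-half uses 0-based trial-index parity (even indices = first half);
half scores are intrusion proportions and the raw half correlation is
corrected with Spearman–Brown `r′ = 2r/(1+r)` (undefined at r = −1).
Cronbach's alpha aligns items by within-participant trial rank and uses
sample (ddof = 1) variances throughout, making it exactly KR-20 on binary
items — an identity the tests assert against an independent KR-20
implementation. Zero-variance halves or total scores raise a distinct
undefined-result signal rather than leaking NaN.

The down-sampling grid samples n participants and t trials uniformly
without replacement (trial order preserved), computes split-half → r′ and
alpha per iteration, and averages over iterations where each statistic is
defined; undefined iterations are dropped, not imputed — imputation would
bias small-n cells, and per-cell valid-iteration counts keep the behavior
auditable. Each cell owns an independent counter-based RNG stream
(`SeedSequence(seed, spawn_key=(i, j))`), so single cells are reproducible
in isolation and the whole grid is reproducible from one seed. The
analysis driver runs participants 10–100 and trials 20–80, both in steps
of 2 (the trial step is stated for the original procedure; the participant
step is chosen symmetric), 100 iterations per cell — ~143k subsamples,
about half a minute on one CPU. Derived measures (AB magnitude, RT
effects) get split-half reliability by scoring each half fully (e.g.,
lag7 − lag3 within the half) before correlating.

## Association statistics

Correlations use pairwise-complete deletion per pair (not listwise),
matching per-measure exclusion bookkeeping; p-values are two-sided from the
t transform. The partial correlation is the first-order formula with
df = n − 3. The Fisher comparison is
`Z = (atanh r₂ − atanh r₁) / √(1/(n₁−3) + 1/(n₂−3))`.

The correlation Bayes factor integrates the likelihood ratio
`f(r|ρ,n) / f(r|0,n)` — with f the exact sampling density of the Pearson
correlation under bivariate normality; only its ρ-dependent factors
`(1−ρ²)^((n−1)/2) (1−ρr)^(−(n−3/2)) ₂F₁(½,½;n−½;(1+ρr)/2)` are needed, as
constants cancel in the ratio — against the stretched-beta prior
`ρ = 2·Beta(1/κ, 1/κ) − 1` (κ = 1: uniform), truncated and renormalized to
one sign for directional hypotheses. Adaptive quadrature at relative
tolerance 1e−9 with a 1e−6 acceptance guard; non-convergence raises a
numeric-failure signal. Directional BFs are the default for confirmatory
hypotheses (direction recorded in output); the robustness sweep over
κ ∈ {0.5, 1.0, 1.5} is written alongside. The t-test BF is the standard
JZS form — a Cauchy(0, √2/2) prior on the standardized effect integrated
through the noncentral-t likelihood, quadrature split at the likelihood
peak so narrow modes are never stepped over. Both BFs are cross-checked in
the tests against an independent closed-form/g-integral implementation
(pingouin), which serves as oracle only.

## Power planners

The two-group planner computes exact power from the noncentral-t
distribution (noncentrality `d·√(n/2)`, d = Δ/σ) and returns the smallest
integer n per group achieving the target (bisection; the minimality is
tested by evaluating power at n−1 and n). It depends on (Δ, σ) only
through d. The correlation planner uses the Fisher-z approximation
`Φ(√(n−3)·atanh ρ − z_crit) ≥ power` and records `method: fisher_z` in its
output, because published correlation sample sizes differ across software
and tail conventions — the widely-quoted figure of 34 for ρ = .40 cannot
be pinned to a stated algorithm or tail choice, so this package documents
its own (n = 38, one-tailed) instead of chasing an unverifiable number.
Searches past the configured cap (default 100,000) raise a capped-result
signal.

## Numerical and I/O conventions

0-based `trial_index`; angles in [0, 360) (360.0 rejected); RT in floating
ms, required positive; lag ∈ {3, 7} on two-target rows. Hard schema
violations abort with row numbers; missing covariates warn and flag. One
top-level seed governs every stage (profiles, each trial table, each grid
cell); two runs of the full report with the same configuration produce
byte-identical artifacts, which the tests verify file by file.

## Problem sizes used by the test suite

Monte-Carlo checks run at the sizes where their tolerances are meaningful:
moment calibration at n = 10,000 (±.01); oracle and recovery checks at
n = 5,000 participants with deliberately long measurement (240 DI, 480 AB,
200 time, 120 RT trials) so binomial/trial noise attenuates latent
correlation targets by well under the ±.05 tolerance; the down-sampling
acceptance cell uses the study-scale 100 × 80 cohort with 100 iterations.
These lengths are analysis choices documented here, not properties of the
emulated tasks.

## Known limitations

- The generator's independence assumptions (one common factor,
  trait-independent age, no session attrition) are idealizations; real
  correlation matrices need not be one-factor.
- Alpha aligns items by trial rank, which is only meaningful when trials
  are exchangeable — true in the generator, approximate in real tasks.
- The stretched-beta BF assumes bivariate normality of the measures; DI
  rates are bounded proportions, so at extreme propensities the sampling
  density is an approximation.
- No ANOVA-family inference and no mixed-model Bayes factors are provided;
  condition means and effects only.
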