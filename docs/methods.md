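# Methods

This note records the statistical model behind `survscreen`, the defaults
and why they are what they are, what the synthetic cohorts do and do not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer from the code.

## Survival model and statistics

Outcomes are right-censored: each patient contributes a follow-up time in
days and an event flag (death observed). Association tests and models:

* **Two-group log-rank test.** At each distinct event time the observed
  deaths in group 1 are compared with the hypergeometric expectation given
  the at-risk counts; the squared standardised sum of observed-minus-
  expected is χ²₁-distributed under the null. The implementation is
  vectorised across features (each feature defines its own two-group
  patient stratification over a shared survival vector), which is what
  makes ~2·10⁵ tests per platform and round affordable; it agrees with
  `lifelines.statistics.logrank_test` to ~1e−8 in the test suite.
* **Welch t-test** (unequal variances, Welch–Satterthwaite df), two-sided.
  The screening variant is vectorised per feature with missing values
  removed per group; groups with fewer than two values yield a skipped
  feature, not an error.
* **Cox proportional hazards.** The partial likelihood with the Efron
  approximation for tied event times is maximised by Newton–Raphson with
  step-halving. Efron was chosen over Breslow because rounded/tied
  follow-up times do occur in real tables and Efron's bias is smaller at
  the tie rates the generator can produce. The solver is written
  vectorised (suffix cumulative sums over the risk sets, grouped
  reductions over tie sets) because the exhaustive subset search needs
  tens of thousands of small fits per pipeline run; it reproduces
  `lifelines.CoxPHFitter` coefficients and log-likelihood to the latter's
  own stopping precision and is itself converged to gradient ~1e−11.
* **Harrell's concordance index.** Comparable pairs are ordered pairs
  (i, j) with an observed event in i and tᵢ < tⱼ strictly; pairs tied in
  time are not comparable (censored-at-equal-time included); tied risks
  count ½. The O(n²) vectorised counter is checked against a brute-force
  pair enumerator on random censored cohorts.

Numerical choices for the Cox solver: start at β = 0; convergence when the
relative negative-log-likelihood change is < 1e−9 *and* the gradient is
below 1e−6 (relative), at most 50 iterations with up to 30 halvings per
step; the linear predictor is shifted by its maximum before
exponentiation (the partial likelihood is invariant to this). A monotone
likelihood (perfect risk separation) is detected as |β| exceeding 15 per
standardised covariate unit — far beyond any plausible hazard ratio — and
flagged rather than raised; flagged fits are excluded from the model
search with a logged reason. A singular information matrix (collinear
covariates) is flagged the same way.

## Marker screening

All tunables live in `SelectionConfig`; defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_iterations` | 100 | random split-half iterations per approach |
| `z_extreme` | 1.0 | \|Z\| threshold of the extreme-score strata |
| `z_mean` | 0.0 | threshold of the mean-score strata |
| `min_group` | 10 | minimum patients per stratum (per half) |
| `alpha` | 0.05 | two-sided significance level of both screens |
| `short_survival_days` | 365 | "died within the first year" horizon |
| `long_survival_days` | 1825 | "lived longer than five years" horizon |
| `top_k` | 10 | markers kept per approach |

Decisions the procedure descriptions leave open, resolved here:

* One half-split per iteration, shared by all features of a platform (the
  natural reading, and ~100× cheaper than per-feature splits). Splits are
  drawn over the lexicographically sorted patient ids, so results are
  invariant to row order.
* Z = 0 exactly goes to the low group of the mean-score screen (a
  deterministic rule for a measure-zero event); the extreme screen uses
  the strict inequalities Z > 1 and Z < −1.
* "Died within the first year" requires an observed event at t ≤ 365;
  "lived longer than five years" is t > 1825 whether or not the patient
  later died; a patient censored before day 365 is in neither group.
* Iterations whose halves lack 10 short- or 10 long-survivors are skipped
  for all features and removed from the frequency denominator
  (`n_iterations_effective` is reported alongside each frequency).
* Top-k ties break by frequency (desc), then mean p-value over passing
  iterations (asc), then feature id — deterministic and reportable.
* A marker's direction of association is the majority survival ordering
  across its passing iterations (sign of the summed observed-minus-
  expected deaths of the high group, or of the t statistic); split
  majorities are reported `undetermined`, not guessed.
* Z-scores are fitted on the **training** cohort only and applied frozen
  to the test cohort. Standardising on the pooled cohort would leak test
  information into the strata; results may differ slightly from an
  analysis that pooled.
* No multiple-testing correction across features: the split-half
  replication at raw p < 0.05 *is* the error control of the screening
  design, and the null-calibration tests quantify what it delivers (a
  per-feature per-iteration pass probability ≤ α²).

## Model search and integration

* "Best at rank r" means highest training C-index; AIC only breaks ties
  (then lexicographic covariate names). Subsets are streamed from
  `itertools.combinations`; `max_subsets` caps the enumeration with a
  logged downgrade for pools where C(30, 6) would be excessive.
* Complete-case handling: each candidate subset is fitted and scored on
  the patients with complete covariates *for that subset* (platform
  missingness is whole-patient, so within one platform all subsets see the
  same rows). Missing values are never imputed.
* Backward AIC elimination fixes the analysis rows to the complete cases
  of the initial full model for the whole elimination path — AIC values
  are only comparable on a fixed dataset (R's `stepAIC` enforces the same
  thing by erroring). Elimination may run down to the null model; the AIC
  trace is strictly decreasing by construction and is exposed for audit.
  If the initial model cannot be fitted (collinearity, too few rows), the
  model falls back to the clinical covariates with a logged warning.
* Clinical covariates enter as single numeric columns: gender 0/1, age in
  years, grade and stage as integer codes 1–4 (the smallest model
  consistent with treating grade and stage as single features; ordinal
  dummy coding would quadruple the parameter count).
* Raw (unscaled) covariates enter the integration models; Cox estimates
  are equivariant under per-covariate rescaling, so only interpretation,
  not selection, would change.
* The multi-omics model takes the union of the per-platform combined
  marker lists with platform-prefixed names (`mrna:gene-0042`), which also
  disambiguates id collisions across platforms.

## Cross-validation

Patients are sorted by time (ties: deceased before censored, then id) and
dealt round-robin into k = 3 sets, giving sizes that differ by at most one
(178/178/177 at n = 533) and near-identical survival distributions per
set. The assignment is fully deterministic given the clinical table, so no
seed enters it. One master seed derives per-round and per-selector seeds
through `numpy.random.SeedSequence.spawn`, making the full pipeline
bit-reproducible and each sub-component reproducible in isolation.
Training for a round receives a cohort object containing only training
patients — test leakage is prevented structurally, and a test corrupts the
held-out set to prove fitted models cannot change. Cross-round dispersion
is the sample standard deviation over the k = 3 test values; with three
observations it is an unstable estimate and is reported as such, not as a
confidence interval.

## Synthetic cohorts

`simulate_cohort` draws, per patient: gender ~ Bernoulli(½); age ~
N(60, 12²) clipped to [25, 90]; stage with probabilities (0.50, 0.11,
0.24, 0.16) and grade (0.25, 0.40, 0.25, 0.10). Event times follow a
Weibull proportional-hazards mechanism, T = scale·(E/exp(lp))^(1/shape)
with E ~ Exp(1), shape 1.1 and scale 2500 days; `lp` adds the clinical
terms (defaults: 0.1·gender + 0.3·(age−60)/10 + 0.3·(grade−2) +
0.5·(stage−2.1)) and one β·z term per planted marker, where z ~ N(0, 1) is
the marker's latent score. Censoring is an independent uniform horizon
whose scale is solved by bisection so the expected censoring fraction hits
the target (default 357/533 ≈ 0.67, the motivating cohort's alive
fraction); any target strictly inside (0, 1) is achievable, anything else
is rejected.

Observed features are monotone maps of the latent scores: identity for
expression platforms (all other features i.i.d. N(0, 1)); a logistic
transform for methylation (beta values in (0, 1), feature-level intercepts
~ N(0, 0.8)); 0.3·z written into a dedicated genomic segment for copy
number, with the rest of each patient's genome tiled by Poisson-random
segments with N(0, 0.25) means, so the gene-level value must be recovered
through the interval-overlap mapping; Bernoulli carrier status for
mutation genes (rates U(0.01, 0.12), planted genes ≥ 0.10). Stage-coupled
methylation markers add `stage_coupling`·(stage − mean stage) latent
units; methylation–expression pairs share one latent score with a sign
flip, and normal-tissue companions shift the paired methylation latent by
+1.5 (normal tissue hypermethylated, tumors hypomethylated with high
paired expression). Platform missingness masks whole patients (defaults
mirror a published per-platform availability table, e.g. 518/533 for mRNA,
477/533 for methylation); scattered cell-level missingness is available as
an option to exercise the more-than-half-observed feature filter.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real cohorts: co-expression/LD structure among
features (each non-planted feature is independent noise, so selection
frequencies are optimistic relative to correlated real data), copy-number
breakpoint realism, batch effects, informative censoring, and
non-proportional hazards. The generator satisfies the Cox assumption by
construction; it measures whether the pipeline recovers what its own model
class can express, not whether that model class fits any particular tumor
cohort.

## Test and reference problem sizes

The package's own test scale, chosen to exercise the full machinery on
realistic cohort dimensions: null calibration runs 533 patients × 500
features on all six platforms with 100 selection iterations and 3 CV
rounds, with the rank sweep capped at 3 (2 for the combined pool) —
calibration of the test C-index does not change with rank; planted-marker
recovery runs ten independent 533-patient cohorts with two markers at
β = log 3 through mean-score selection and the rank-2 search; exhaustive
cross-checks of the subset search use pools of 10 candidates (ranks 1–4)
against an independently coded lifelines enumeration, and backward AIC is
compared against complete enumeration of all 2¹⁰ subsets. The reference
script reports the random-risk concordance (500 patients, 30% censoring,
100 uniform risk replicates), whose expectation is the no-information
value ½.

## Known limitations

* The C-index tie conventions and the Efron tie handling are one of
  several defensible choices; third-decimal differences against other
  implementations are expected on heavily tied data.
* Backward elimination is greedy: its final AIC is bounded below by, but
  need not equal, the exhaustive-subset minimum (asserted, not assumed, in
  the tests).
* With k = 3 the reported standard deviations rest on three values.
* Single-process execution; the streamed subset search is the intended
  hook for parallelism if ever needed.
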