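# survscreen

Cross-omics survival-marker screening and prediction for censored patient
cohorts.

`survscreen` implements, as a tested and reusable pipeline, a strategy for
asking which molecular platform — miRNA/mRNA/protein expression, DNA
methylation, copy number, somatic mutations — best predicts overall survival
in a tumor cohort, and whether molecular markers add prognostic power beyond
routine clinical variables (gender, age, tumor grade, tumor stage). It is
aimed at biostatisticians and computational biologists working with
TCGA-style cohorts: a clinical table with right-censored follow-up plus
per-platform feature matrices with realistic patient-level missingness.

## The method

**Marker screening.** Molecular values are Z-scored against the training
cohort's tumor samples. Three stratification approaches screen every
feature, each repeated over 100 random split-half iterations of the
training cohort:

* *extreme score*: patients with Z > 1 versus Z < −1, two-group log-rank
  test (significant at p < 0.05 in both halves, both groups ≥ 10 patients);
* *mean score*: the same machinery with the threshold at Z = 0;
* *extreme survival*: patients who died within the first year versus
  patients who lived longer than five years, Welch t-test on the feature's
  raw values in both halves.

Features are ranked by their selection frequency over the 100 iterations
and the top 10 per approach are kept; the *combined* approach is the union
of the three lists (up to 30 candidates). Somatic mutations are screened by
a single carrier-versus-non-carrier log-rank test per gene.

**Model search.** For each approach and each model rank r, every size-r
subset of the candidate markers is fitted as a Cox proportional-hazards
model (Efron tie handling) on the training cohort; the subset with the
highest training concordance index

C = (concordant + ½·tied) / comparable pairs, over pairs (i, j) with an
observed event in i and tᵢ < tⱼ (Harrell's rule),

wins the rank (r = 1..10; 1..6 for the combined pool, whose C(30, 6) ≈
6·10⁵ subsets are streamed, never materialised). Clinical integration
starts from all markers plus the four clinical covariates and removes one
covariate at a time by backward AIC (AIC = −2·log partial likelihood +
2·k) until no removal lowers it; the multi-omics model applies the same
elimination to the platform-prefixed union of all marker lists.

**Validation.** Patients are sorted by survival/follow-up time and dealt
round-robin into three equally sized sets (e.g. 178/178/177 at n = 533), so
the sets are balanced in survival time and vital status; every model is
trained on two sets and scored on the held-out third, and performance is
reported as the mean ± sd of the test C-index over the three rounds.

Because real cohort downloads are out of scope, the package ships a
synthetic multi-omics generator (`survscreen.simulate`) with a Weibull
proportional-hazards survival mechanism, planted markers of known log
hazard ratio, beta-valued methylation, segmented copy number, sparse binary
mutations, per-platform whole-patient missingness and normal-tissue
companion samples — every pipeline stage is testable against known ground
truth.

## Worked example

```python
import numpy as np
from survscreen import (SelectionConfig, ModelSearchConfig, run_cv,
                        simulate_cohort, SimulationConfig, PlantedMarker)

cohort = simulate_cohort(SimulationConfig(
    n_patients=533,
    feature_counts={"mrna": 500},
    planted=(PlantedMarker("mrna", 11, np.log(3.0)),
             PlantedMarker("mrna", 42, np.log(3.0))),
    rng_seed=0))

result = run_cv(cohort,
                SelectionConfig(n_iterations=100),
                ModelSearchConfig(max_rank=2, max_rank_combined=2),
                master_seed=1000, platforms=["mrna"],
                approaches=("mean_score",))

top = result.markers[result.markers["round"] == 0].head(3)
print(top[["feature_id", "frequency", "direction"]].to_string(index=False))
print(result.summary.query("approach == 'mean_score'")
      [["rank", "train_c_mean", "test_c_mean", "test_c_sd"]]
      .to_string(index=False))
```

prints

```
feature_id  frequency   direction
 gene-0011        100  high_worse
 gene-0042        100  high_worse
 gene-0214         38 high_better
 rank  train_c_mean  test_c_mean  test_c_sd
    1      0.727901     0.727257   0.031583
    2      0.802885     0.803873   0.037580
```

The two planted markers (true hazard ratio 3 per standard deviation) are
selected in every resampling iteration of round 0 and direction-called
correctly (high expression, worse outcome); the best rank-2 model reaches a
cross-validated test C-index of ≈ 0.80, against 0.5 for random guessing.
The same machinery is available from the shell:

```bash
survscreen simulate --out-dir cohort/ --seed 1
survscreen run-all --cohort-dir cohort/ --out-dir results/ --seed 1
survscreen report --cohort-dir cohort/ --summary results/summary.tsv --out-dir report/
```

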