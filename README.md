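# twinherit

Heritability estimation for multivariate behavioral phenotypes from twin
cohorts — with a built-in simulator so every estimator can be validated by
parameter recovery against known ground truth.

## The problem

In the classical twin design, the variance of a standardized trait is
decomposed into additive genetic (A), common-environment (C), non-additive
genetic (D) and unique-environment (E) fractions. Within a twin pair the
components correlate at textbook values — A at 1.0 for monozygotic (MZ)
twins and 0.5 for dizygotic (DZ) twins, D at 1.0 / 0.25, C at 1.0 for both,
E at 0 — so the trait-level twin correlations identify the components.
Falconer's formula gives the additive heritability

    h² = 2 (r_MZ − r_DZ)

with the convention that r_MZ > 2·r_DZ implicates non-additive effects (ADE
model; r_MZ itself is then the broad genetic estimate) and r_MZ < r_DZ flags
a "negative heritability" with no fitting genetic model.

Beyond this classical estimator, the package implements a complementary,
data-driven family: classifiers trained to separate MZ from DZ twin pairs on
the absolute z-scored within-pair difference of each measure. If a measure
is heritable, MZ pairs differ less on it than DZ pairs, so a good classifier
weights it heavily; the absolute feature weights (univariate OLS slope,
ridge coefficients, random-forest Gini importances) serve as qualitative
heritability profiles that can be rank-compared with the Falconer profile.

Around this core the package provides:

* **Behavioral fingerprinting** — nearest-neighbour re-identification of a
  subject (from retest data) or their MZ co-twin by Euclidean distance over
  the measure profile, with a shuffled-identity permutation null.
* **Bivariate genetic correlation** — the decomposition
  ρ_P = √(h²_a h²_b)·ρ_G + √((1−h²_a)(1−h²_b))·ρ_E, with ρ_G identified
  from the cross-twin cross-trait MZ/DZ contrast (a moment estimator; no
  pedigree likelihood machinery).
* **Exploratory factor analysis** — principal axis factoring, Kaiser
  retention, Promax rotation, regression and Bartlett factor scores, and a
  factor-level rerun of every heritability method.
* **Inference** — permutation nulls for identification, bootstrap CIs and
  p-values for classification accuracy, and a Monte Carlo permutation test
  for the task-vs-questionnaire domain contrast.
* **A twin-cohort simulator** (`twinherit.synthetic_data`) that generates
  phenotypes from explicit `VarianceSpec` ground truth, including
  cross-measure genetic correlation, retest occasions calibrated to a target
  test-retest reliability, and age/sex covariate hooks.

Intended users: behavioral geneticists and methodologists who want a
transparent, fully testable desk-scale pipeline — e.g. to study estimator
behavior under known variance components before touching restricted data.

## Worked example

```python
import numpy as np
from twinherit import (CohortDesign, VarianceSpec, simulate_cohort,
                       build_pair_features, ridge_classify, univariate_weights,
                       RunConfig, identify_self, spearman_matrix)
from twinherit.heritability import falconer_profile

specs = [
    VarianceSpec("matrix_reasoning", a2=0.6, e2=0.4, domain="task"),
    VarianceSpec("vocabulary",       a2=0.5, c2=0.2, e2=0.3, domain="task"),
    VarianceSpec("processing_speed", a2=0.3, e2=0.7, domain="task"),
    VarianceSpec("neuroticism",      a2=0.4, e2=0.6, domain="questionnaire"),
    VarianceSpec("life_satisfaction", a2=0.2, c2=0.2, e2=0.6, domain="questionnaire"),
    VarianceSpec("daily_stress",     e2=1.0, domain="questionnaire"),
]
design = CohortDesign(n_measures=6, n_mz_pairs=149, n_dz_pairs=90,
                      n_unrelated=700, n_retest=46, seed=0)
cohort = simulate_cohort(design, specs)

res = identify_self(cohort, n_perm=1000, seed=0)
print(f"self-identification: {res.accuracy:.1%} ({res.n_correct}/{res.n_targets}), "
      f"median rank {res.median_rank:.1f}, p {res.p_report}")

prof = falconer_profile(cohort)
print(prof.table[["rMZ", "rDZ", "model", "h2"]].round(3))

pairset = build_pair_features(cohort)
perf, ridge_w, alpha = ridge_classify(
    pairset, RunConfig(seed=0, n_iterations=1000, n_alpha_iterations=100))
print(f"ridge: mean accuracy {perf.mean_accuracy:.1%}, "
      f"95% CI [{perf.ci95[0]:.1%}, {perf.ci95[1]:.1%}], "
      f"bootstrap p {perf.p_report}, alpha {alpha}")

agreement = spearman_matrix({
    "falconer": prof.values.to_numpy(float),
    "univariate": univariate_weights(pairset).mean.to_numpy(),
    "ridge": ridge_w.mean.to_numpy(),
})
print(agreement.round(2))
```

Output:

```
self-identification: 100.0% (46/46), median rank 1.0, p < 0.001
                        rMZ       rDZ model        h2
matrix_reasoning   0.645127  0.359443   ACE  0.571368
vocabulary         0.641484  0.402847   ACE  0.477273
processing_speed   0.268839  0.057955   ADE  0.268839
neuroticism        0.309596  0.260501   ACE  0.098189
life_satisfaction   0.44603  0.240351   ACE  0.411358
daily_stress      -0.139151 -0.051668  NONE -0.174966
ridge: mean accuracy 61.9%, 95% CI [52.2%, 71.1%], bootstrap p 0.008, alpha 1.0
            falconer  univariate  ridge
falconer        1.00        0.89   0.89
univariate      0.89        1.00   1.00
ridge           0.89        1.00   1.00
```

Reading it: with perfect test-retest reliability, every one of the 46 retest
subjects is re-identified (no permutation came close, so p is reported at
the 1/1000 floor). The Falconer table recovers the planted structure at this
sample size (149 + 90 pairs): strongly heritable measures land near their
true a², `processing_speed` happens to draw r_MZ > 2·r_DZ and is classified
ADE, and the pure-noise `daily_stress` shows the negative-heritability
pattern. The ridge classifier separates MZ from DZ pairs at 61.9% (CI
excluding 50%), and its weight profile rank-agrees with the classical
estimates at ρ ≈ 0.9.

The same flow is available end-to-end from a YAML config:

```bash
twinherit run config.yaml --seed 1 --out results/
twinherit fingerprint config.yaml --mode twin
twinherit mlweights config.yaml --model rf
```

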