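# Methods

## The generative model

Each measure `j` has a ground-truth `VarianceSpec` with non-negative
fractions `a2 + c2 + d2 + e2 = 1` and `c2 * d2 = 0`: the classical twin
design can identify at most three components at once, so every measure is
either an ACE or an ADE model. The stable trait of subject `i` is

    T_ij = sqrt(a2_j) A_ij + sqrt(c2_j) C_ij + sqrt(d2_j) D_ij + sqrt(e2_j) E_ij

with all components standard normal. Within a twin pair the components
correlate at the design values (A: 1.0 MZ / 0.5 DZ; D: 1.0 / 0.25; C: 1.0 /
1.0; E: 0 / 0), implemented by the mixture `x2 = r*x1 + sqrt(1-r^2)*u` so
each twin's marginal stays standard normal. Closed forms follow directly:
`rMZ = a2 + d2 + c2`, `rDZ = a2/2 + d2/4 + c2` (`expected_twin_correlations`).

Cross-measure structure is imposed on the A components only, through a
user-supplied genetic correlation matrix (or a factor-loading recipe,
`loading_corr`); C, D and E are independent across measures by default, with
an optional environmental correlation matrix on E. Unrelated singletons draw
all components independently.

**Measurement occasions.** The observed phenotype is
`sqrt(rel) * T + sqrt(1-rel) * occasion_noise`, and a retest row re-draws
only the occasion noise, so the expected test-retest Pearson correlation
equals the spec's `reliability` exactly. Consequence worth knowing: measured
twin correlations are attenuated by `rel` relative to the trait-level closed
forms. The default is `reliability = 1.0` (no occasion noise), and all
parameter-recovery results in the test suite use that default; reliability
below 1 is exercised where it is the object of study (retest calibration,
fingerprinting noise curves, disattenuation).

**Covariates.** Age (uniform integers 22–35) and sex (balanced binary) are
generated independent of the phenotypes. An optional `covariate_betas`
recipe adds linear age/sex effects, existing solely so the residualization
step can be tested against a known planted effect; the default of "no
covariate effect" is a modeling choice, not an inference about any dataset.

All randomness flows from the single `CohortDesign.seed` through
`numpy.random.SeedSequence.spawn`, split by component block; identical
design + specs give a bit-identical cohort.

## What the simulator does and does not emulate

It reproduces the *structure* a twin analysis consumes: MZ/DZ pairs sharing
a family id, unrelated singletons, a retest subsample (drawn from the MZ
subjects), per-measure variance components, genetic correlation across
measures, and occasion noise. It does not emulate distributional quirks of
real behavioral scores (skew, floors/ceilings, ordinal scales), missing
data, assortative mating, gene–environment interaction, or non-twin
pedigree structure. Passing recovery tests therefore demonstrates estimator
correctness under the model's own assumptions — not robustness to the ways
real data violate them.

## Estimator conventions

* **Twin correlations** are Pearson correlations on double-entered pairs
  (each pair contributes both orderings), making them invariant to
  within-pair order — close in spirit to an intraclass correlation.
* **Falconer selection rule**: `rMZ < rDZ` → model NONE, the (negative)
  `2*(rMZ-rDZ)` value is kept and flagged; `rMZ <= 2*rDZ` → ACE with
  `h2 = 2*(rMZ-rDZ)` (the boundary ties to ACE, dominance assumed
  negligible there); `rMZ > 2*rDZ` → ADE with headline `h2 = rMZ`, and the
  Falconer-form value stored alongside because either may be wanted
  downstream.
* **Disattenuation** divides by test-retest reliability; corrected values
  above 1 are flagged as inflated rather than truncated.
* **Genetic correlation** uses the cross-twin cross-trait moment estimator:
  genetic covariance `= 2*(ctct_MZ - ctct_DZ)` on residualized,
  rank-inverse-normal-transformed, z-scored measures;
  `rho_G = gcov / sqrt(h2_a h2_b)` clamped to [-1, 1] (clamps logged per
  cell), `rho_E` solved from the decomposition so recomposition is exact
  when unclamped. Heritability inputs come from the Falconer stage,
  truncated to [0.01, 0.99]; raw values outside (0, 1) mask the cell with a
  reason code. This is a deliberate, desk-scale substitution for pedigree
  maximum likelihood: assumption-matched to the rest of the pipeline, twin
  pairs only, no external solver.
* **Inverse normal transform** is Blom's rank-based form
  `Phi^-1((rank - 3/8)/(n + 1/4))` with average ranks for ties — a
  documented constant choice among the rank-offset family.
* **Covariate design** is `[1, age, sex, age*sex, age^2, age^2*sex]`; a
  rank-deficient design errors listing the collinear columns.

## The classification pipeline

Features are `|z(twin1) - z(twin2)|` per measure per pair, labels +1 (MZ) /
-1 (DZ). Z-scores are computed over the full cohort before any split — a
deliberate replication of the emulated procedure (the leakage is known and
shared by it); `strict_split` addresses the larger split leakage below.

Each bootstrap iteration draws {oversample-balance, stratified 70/30 split,
fit, score}; degenerate single-class partitions are redrawn (counted in the
summary). Three models:

* univariate OLS of the label on each single feature (absolute slope;
  informative slopes are negative since MZ differences are smaller);
* a ridge classifier run in two phases — per-iteration 5-fold
  cross-validated selection over the alpha grid
  (200, 100, 10, 1, 0.1, 0.01, 0.001), then the full bootstrap at the modal
  alpha (fold count and stratification are package choices; both
  documented here rather than inherited);
* a random forest (100 trees, depth 5, sqrt-features per split, Gini
  impurity importances, ROC AUC tracked). `rf_tune` reproduces the
  out-of-bag tuning surface over trees x depth x max-features.

Performance summaries report the mean accuracy, the 2.5/97.5 percentile CI,
and a bootstrap p-value `#{accuracy <= 0.5}/n`, floored at `1/n` and
reported as `"< 1/n"` when the count is zero. The Haufe transform
(`pattern = feature_covariance @ weights`) converts decoder weights into
forward-model activations, deflating suppressor features.

**Split-order leakage, quantified.** The default order (balance, then
split) faithfully mirrors the emulated procedure but lets duplicated
minority rows cross the split. Measured on pure-noise cohorts (100 cohorts
x 20 iterations, ridge, alpha 100): the default order yields 52.9% mean
"null" accuracy, and a single 239-pair cohort additionally carries
accidental class structure with a cohort-level sd of ~3.4 points.
`strict_split=True` splits first and then balances train and test
separately — no row crosses the split and the test set is balanced — giving
49.98% on the same experiment, i.e. exactly the nominal chance level.
Chance-level validation therefore uses `strict_split` averaged over
independent null cohorts (20 cohorts x 50 iterations in the acceptance
measurements); signal-bearing results are reported under the faithful
default unless noted.

## Factor analysis

Principal axis factoring iterates eigendecomposition of the
communality-reduced correlation matrix from squared-multiple-correlation
starts until the largest communality change falls below 1e-4 (cap 100
iterations; non-convergence warns and returns the last iterate; Heywood
communalities clip to 0.999 with a warning). The Kaiser rule counts
eigenvalues of the *unreduced* correlation matrix strictly above 1 — the
SPSS convention — so an identity correlation matrix retains zero factors;
an explicit `n_factors` overrides it. Promax uses a Kaiser-normalized
varimax pre-rotation, a power-4 target (kappa = 4, the SPSS default), an
oblique Procrustes fit, and rescales so implied factor variances are 1;
factor sign is fixed by making each factor's largest-magnitude loading
positive. Regression (Thurstone) scores use `R^{-1} Lambda Phi` weights
(ridge-stabilized at 1e-8 if `R` is singular, with a warning); Bartlett
scores use uniqueness-weighted least squares. The pipeline's factor stage
reruns Falconer and all three classifiers on regression scores, and runs
the concatenated regression+Bartlett score set through ridge and forest as
a correlated-feature robustness probe.

## Statistics

Cross-method agreement is a Spearman matrix with average-rank ties; entries
involving constant profiles are masked. The domain test statistic is the
absolute difference between task and questionnaire mean estimates; the null
reassigns measures to domains preserving group sizes, by Monte Carlo
(default 100,000 draws) or exhaustively when the label space is small. "At
least as extreme" uses `>=` and the reported p is never exactly zero. The
report carries both the uncorrected per-profile p-values and a Bonferroni
adjustment across the profile family, labeled as such.

## Problem sizes and tolerances

Recovery tests are sized so that Monte Carlo error is well inside the
asserted tolerance: twin-correlation fidelity at 10,000 pairs (SE < 0.01),
Falconer recovery at 5,000 + 5,000 pairs averaged over seeds (a single draw
has SE(h2) ~ 0.035, so seed means are the stable quantity for a +/-0.05
check), genetic-correlation recovery at 5,000–10,000 pairs, chance-level
classification at 1000 iterations spread over 20 independent null cohorts
(cohort-level accidental structure dominates the error otherwise), and the
weight-profile agreement design at 12 measures x 2,000 + 2,000 pairs with
the forest at 100 iterations (importance means stabilize far earlier than
accuracy percentiles; ridge and univariate run the full 1000).

## Known limitations

* The genetic-correlation stage is a moment estimator: no standard errors
  or likelihood-ratio tests, and non-twin relatives are ignored.
* Negative or >1 heritability inputs mask genetic-correlation cells rather
  than being modeled; clamping ρ_G discards information beyond the bound.
* The simulator's Gaussian, complete-case world understates the difficulties
  of real behavioral data (see above).
* Bootstrap CIs for classification accuracy describe re-split variability of
  one cohort, not sampling variability across cohorts — the latter is
  several points wide at 239 pairs, which is worth remembering when reading
  any single cohort's accuracy.
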