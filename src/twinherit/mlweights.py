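"""MZ-vs-DZ pair classification and classifier-weight heritability proxies.

If twin-pair differences on a measure shrink with genetic relatedness, a
classifier separating MZ from DZ pairs on absolute z-scored pair differences
should weight heritable measures more heavily.  Three models are run over
bootstrap iterations of {oversample-balance, 70/30 split, fit, score}:

* univariate OLS of the +/-1 label on each single feature (max contribution
  of a feature in isolation; informative slopes are negative because MZ
  differences are smaller, so absolute slopes are reported),
* an L2-penalized (ridge) linear classifier whose regularization strength is
  first chosen by per-iteration internal cross-validation and then fixed at
  the modal choice,
* a random forest (100 trees, depth 5, sqrt-features) whose Gini
  mean-decrease-impurity importances are averaged across iterations, with
  ROC AUC tracked alongside accuracy.

Oversampling happens *before* the split inside each iteration, faithfully
reproducing the emulated procedure even though duplicated minority rows may
then cross the split; ``strict_split=True`` reverses the order for a
leakage-free evaluation.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import RidgeClassifier, RidgeClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .preprocess import PairFeatureSet, oversample_balance


class MLWeightsError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the bootstrap classification pipeline (defaults mirror the
    emulated study: 1000 iterations, 70/30 split, the published alpha grid
    and forest shape)."""

    n_iterations: int = 1000
    test_fraction: float = 0.3
    alpha_grid: tuple = (200, 100, 10, 1, 0.1, 0.01, 0.001)
    rf_n_trees: int = 100
    rf_max_depth: int | None = 5
    rf_max_features: str = "sqrt"
    cv_folds: int = 5
    n_alpha_iterations: int | None = None  # defaults to n_iterations
    strict_split: bool = False
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise MLWeightsError("test_fraction must be in (0, 1)")
        if self.n_iterations < 1 or not self.alpha_grid:
            raise MLWeightsError("n_iterations >= 1 and non-empty alpha_grid required")


@dataclass
class WeightProfile:
    """Per-feature mean and sd of |coefficient| or impurity importance."""

    method: str
    mean: pd.Series
    sd: pd.Series

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"mean": self.mean, "sd": self.sd, "method": self.method})
        out.index.name = "feature"
        out.to_csv(path, sep="\t")


@dataclass
class PerformanceSummary:
    mean_accuracy: float
    ci95: tuple[float, float]
    bootstrap_p: float
    p_report: str
    n_iterations: int
    accuracies: np.ndarray = field(repr=False, default=None)
    mean_auc: float | None = None
    sd_auc: float | None = None
    n_redrawn: int = 0

    def summary(self) -> dict:
        out = {
            "mean_accuracy": self.mean_accuracy,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "bootstrap_p": self.bootstrap_p,
            "p_report": self.p_report,
            "n_iterations": self.n_iterations,
        }
        if self.mean_auc is not None:
            out["mean_auc"] = self.mean_auc
            out["sd_auc"] = self.sd_auc
        return out


def summarize_performance(accuracies: np.ndarray,
                          aucs: np.ndarray | None = None,
                          n_redrawn: int = 0) -> PerformanceSummary:
    """Mean accuracy, percentile 95% CI and the bootstrap p-value.

    ``bootstrap_p`` is the fraction of iterations with test accuracy <= 0.5
    (chance for a balanced binary problem); a zero count is reported as
    ``"< 1/n"`` and floored at ``1/n`` rather than 0.
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size < 2:
        raise MLWeightsError("need >= 2 accuracy values to summarize")
    n = accuracies.size
    count = int((accuracies <= 0.5).sum())
    if count == 0:
        p, report = 1.0 / n, f"< {1.0 / n:g}"
    else:
        p, report = count / n, f"{count / n:g}"
    summary = PerformanceSummary(
        mean_accuracy=float(accuracies.mean()),
        ci95=(float(np.percentile(accuracies, 2.5)),
              float(np.percentile(accuracies, 97.5))),
        bootstrap_p=p,
        p_report=report,
        n_iterations=n,
        accuracies=accuracies,
        n_redrawn=n_redrawn,
    )
    if aucs is not None:
        aucs = np.asarray(aucs, dtype=float)
        summary.mean_auc = float(aucs.mean())
        summary.sd_auc = float(aucs.std())
    return summary


def univariate_weights(pairset: PairFeatureSet) -> WeightProfile:
    """|slope| of a single-feature OLS of the +/-1 label on each feature.

    The slope is ``cov(x, y) / var(x)``; constant features get weight 0 with
    a warning.  No bootstrap is needed — the fit is deterministic given the
    (balanced) pairset.
    """
    x = pairset.features.to_numpy(float)
    y = pairset.labels.astype(float)
    yc = y - y.mean()
    means = {}
    for j, name in enumerate(pairset.features.columns):
        xj = x[:, j]
        var = xj.var()
        if var == 0.0:
            warnings.warn(f"constant feature {name!r}: univariate weight set to 0")
            means[name] = 0.0
            continue
        slope = float(((xj - xj.mean()) * yc).mean() / var)
        means[name] = abs(slope)
    mean = pd.Series(means)
    return WeightProfile(method="univariate", mean=mean,
                         sd=pd.Series(0.0, index=mean.index))


def univariate_slopes(pairset: PairFeatureSet) -> pd.Series:
    """Signed single-feature OLS slopes (informative features come out
    negative: larger within-pair differences predict DZ = -1)."""
    x = pairset.features.to_numpy(float)
    y = pairset.labels.astype(float)
    yc = y - y.mean()
    out = {}
    for j, name in enumerate(pairset.features.columns):
        xj = x[:, j]
        var = xj.var()
        out[name] = 0.0 if var == 0 else float(((xj - xj.mean()) * yc).mean() / var)
    return pd.Series(out)


def _iteration_data(pairset: PairFeatureSet, config: RunConfig,
                    rng: np.random.Generator):
    """One bootstrap draw: balance + stratified split (redrawn on degenerate
    single-class partitions).  Returns (x_tr, x_te, y_tr, y_te, n_redraws)."""

    def _balance_arrays(x, y):
        part = PairFeatureSet(
            features=pd.DataFrame(x, columns=pairset.features.columns),
            labels=y, pair_ids=[str(i) for i in range(len(y))])
        part = oversample_balance(part, rng)
        return part.features.to_numpy(float), part.labels

    for attempt in range(100):
        if config.strict_split:
            # leakage-free order: split first, then balance each side
            # separately so no duplicated row crosses the split and the test
            # set is balanced (chance accuracy is exactly 50%)
            x = pairset.features.to_numpy(float)
            y = pairset.labels
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=config.test_fraction,
                random_state=int(rng.integers(2**31)),
                stratify=y if config.stratify else None)
            xtr, ytr = _balance_arrays(xtr, ytr)
            xte, yte = _balance_arrays(xte, yte)
        else:
            balanced = oversample_balance(pairset, rng)
            x = balanced.features.to_numpy(float)
            y = balanced.labels
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=config.test_fraction,
                random_state=int(rng.integers(2**31)),
                stratify=y if config.stratify else None)
        if len(np.unique(ytr)) == 2 and len(np.unique(yte)) == 2:
            return xtr, xte, ytr, yte, attempt
    raise MLWeightsError("could not draw a split with both classes present")


def choose_alpha(pairset: PairFeatureSet, config: RunConfig,
                 rng: np.random.Generator | None = None) -> tuple[float, Counter]:
    """Per-iteration cross-validated alpha selection; returns the modal alpha.

    Each iteration rebalances and splits, then a k-fold cross-validated ridge
    classifier on the training portion picks the best alpha from the grid.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_iter = config.n_alpha_iterations or config.n_iterations
    votes: Counter = Counter()
    for _ in range(n_iter):
        xtr, _, ytr, _, _ = _iteration_data(pairset, config, rng)
        model = RidgeClassifierCV(alphas=config.alpha_grid, cv=config.cv_folds)
        model.fit(xtr, ytr)
        votes[float(model.alpha_)] += 1
    modal = votes.most_common(1)[0][0]
    return modal, votes


def ridge_classify(pairset: PairFeatureSet, config: RunConfig | None = None,
                   alpha: float | None = None
                   ) -> tuple[PerformanceSummary, WeightProfile, float]:
    """Two-phase ridge pipeline: modal-alpha selection, then the bootstrap.

    Phase 1 repeats internal CV alpha selection per iteration and takes the
    majority vote (skipped when ``alpha`` is given).  Phase 2 runs
    ``n_iterations`` of {balance, split, fit at the modal alpha, record test
    accuracy and |coefficients|}.
    """
    config = config or RunConfig()
    if pairset.features.shape[1] < 2:
        raise MLWeightsError("ridge needs >= 2 features")
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    if alpha is None:
        alpha, _ = choose_alpha(pairset, config, np.random.default_rng(seeds[0]))
    rng = np.random.default_rng(seeds[1])
    accs = np.empty(config.n_iterations)
    coefs = np.empty((config.n_iterations, pairset.features.shape[1]))
    redraws = 0
    for i in range(config.n_iterations):
        xtr, xte, ytr, yte, nr = _iteration_data(pairset, config, rng)
        redraws += nr
        model = RidgeClassifier(alpha=alpha)
        model.fit(xtr, ytr)
        accs[i] = model.score(xte, yte)
        coefs[i] = np.abs(model.coef_.ravel())
    weights = WeightProfile(
        method="ridge",
        mean=pd.Series(coefs.mean(axis=0), index=pairset.features.columns),
        sd=pd.Series(coefs.std(axis=0), index=pairset.features.columns),
    )
    return summarize_performance(accs, n_redrawn=redraws), weights, float(alpha)


def rf_classify(pairset: PairFeatureSet, config: RunConfig | None = None
                ) -> tuple[PerformanceSummary, WeightProfile]:
    """Random-forest bootstrap: accuracy, ROC AUC and impurity importances."""
    config = config or RunConfig()
    if pairset.features.shape[1] < 2:
        raise MLWeightsError("random forest needs >= 2 features")
    rng = np.random.default_rng(config.seed)
    n_feat = pairset.features.shape[1]
    accs = np.empty(config.n_iterations)
    aucs = np.empty(config.n_iterations)
    imps = np.empty((config.n_iterations, n_feat))
    redraws = 0
    for i in range(config.n_iterations):
        xtr, xte, ytr, yte, nr = _iteration_data(pairset, config, rng)
        redraws += nr
        model = RandomForestClassifier(
            n_estimators=config.rf_n_trees,
            max_depth=config.rf_max_depth,
            max_features=config.rf_max_features,
            random_state=int(rng.integers(2**31)),
        )
        model.fit(xtr, ytr)
        accs[i] = model.score(xte, yte)
        proba = model.predict_proba(xte)[:, list(model.classes_).index(1)]
        aucs[i] = roc_auc_score(yte, proba)
        imps[i] = model.feature_importances_
    weights = WeightProfile(
        method="rf",
        mean=pd.Series(imps.mean(axis=0), index=pairset.features.columns),
        sd=pd.Series(imps.std(axis=0), index=pairset.features.columns),
    )
    return summarize_performance(accs, aucs=aucs, n_redrawn=redraws), weights


def rf_tune(pairset: PairFeatureSet,
            n_trees_grid: tuple = tuple(range(20, 161, 20)),
            max_depth_grid: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, None),
            max_features_grid: tuple = ("sqrt", "log2", None),
            n_reps: int = 100, seed: int = 0) -> pd.DataFrame:
    """Out-of-bag accuracy grid over forest hyperparameters.

    Each cell is the mean OOB accuracy over ``n_reps`` balanced refits.
    ``max_features=None`` means all features (the option expected to do worst
    with correlated features).  Returns a tidy DataFrame with columns
    n_trees, max_depth, max_features, oob_accuracy.
    """
    if len(pairset.labels) < 30:
        raise MLWeightsError("rf_tune needs >= 30 pairs")
    rng = np.random.default_rng(seed)
    rows = []
    for n_trees in n_trees_grid:
        for depth in max_depth_grid:
            for mf in max_features_grid:
                oob = np.empty(n_reps)
                for r in range(n_reps):
                    balanced = oversample_balance(pairset, rng)
                    model = RandomForestClassifier(
                        n_estimators=n_trees, max_depth=depth, max_features=mf,
                        oob_score=True, bootstrap=True,
                        random_state=int(rng.integers(2**31)))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")  # few-tree OOB coverage
                        model.fit(balanced.features.to_numpy(float), balanced.labels)
                    oob[r] = model.oob_score_
                rows.append({"n_trees": n_trees,
                             "max_depth": -1 if depth is None else depth,
                             "max_features": "all" if mf is None else mf,
                             "oob_accuracy": float(oob.mean())})
    return pd.DataFrame(rows)


def haufe_transform(weights: np.ndarray, feature_covariance: np.ndarray) -> np.ndarray:
    """Forward-model activation pattern for linear decoder weights.

    ``pattern = Sigma_x @ w`` (up to positive scaling): a feature's pattern
    value reflects how much the decoded signal expresses in that feature,
    which deflates suppressor features that carry large decoding weights but
    no signal of their own.
    """
    weights = np.asarray(weights, dtype=float).ravel()
    cov = np.asarray(feature_covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1] or cov.shape[0] != weights.size:
        raise MLWeightsError(
            f"covariance shape {cov.shape} does not match {weights.size} weights")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise MLWeightsError("feature covariance must be symmetric")
    if np.linalg.eigvalsh(cov).min() < -1e-8:
        raise MLWeightsError("feature covariance must be positive semidefinite")
    return cov @ weights
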