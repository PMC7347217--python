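"""Classifier-weight heritability proxies: univariate slopes, the two-phase
ridge pipeline, random-forest importances, hyperparameter tuning behavior,
the Haufe forward-model transform, and performance summaries."""

import numpy as np
import pandas as pd
import pytest

from twinherit import (
    CohortDesign,
    RunConfig,
    build_pair_features,
    haufe_transform,
    rf_classify,
    ridge_classify,
    simulate_cohort,
    summarize_performance,
    univariate_weights,
)
from twinherit.mlweights import MLWeightsError, rf_tune, univariate_slopes
from twinherit.preprocess import PairFeatureSet
from tests.conftest import make_specs

FAST = dict(n_iterations=60, n_alpha_iterations=15)


def _signal_pairset(a2_values, n_mz=150, n_dz=90, seed=61):
    specs = make_specs(a2_values)
    design = CohortDesign(len(a2_values), n_mz, n_dz, seed=seed)
    return build_pair_features(simulate_cohort(design, specs))


class TestSummarizePerformance:
    def test_all_chance_gives_p_one(self):
        s = summarize_performance(np.full(100, 0.5))
        assert s.bootstrap_p == 1.0  # "equal to or lower than" includes equality

    def test_all_above_chance_reports_floor(self):
        s = summarize_performance(np.full(1000, 0.7))
        assert s.bootstrap_p == pytest.approx(0.001)
        assert s.p_report == "< 0.001"

    def test_count_fraction(self):
        s = summarize_performance(np.array([0.4, 0.6, 0.6, 0.6]))
        assert s.bootstrap_p == pytest.approx(0.25)

    def test_ci_ordered_and_covering(self):
        rng = np.random.default_rng(0)
        s = summarize_performance(rng.uniform(0.5, 0.9, 500))
        lo, hi = s.ci95
        assert lo <= s.mean_accuracy <= hi


class TestUnivariate:
    def test_uninformative_feature_gets_zero_slope(self):
        rng = np.random.default_rng(1)
        x = np.abs(rng.standard_normal((200, 2)))
        labels = np.array([1, -1] * 100)
        ps = PairFeatureSet(features=pd.DataFrame(x, columns=["a", "b"]),
                            labels=labels, pair_ids=[str(i) for i in range(200)])
        w = univariate_weights(ps)
        assert w.mean["a"] < 0.2 and w.mean["b"] < 0.2

    def test_separating_feature_gets_largest_weight(self):
        ps = _signal_pairset([0.8, 0.0, 0.0, 0.0])
        w = univariate_weights(ps)
        assert w.mean.idxmax() == "m00"

    def test_informative_slopes_are_negative(self):
        # MZ pairs differ less, so larger differences predict the -1 class
        ps = _signal_pairset([0.8, 0.6, 0.0])
        slopes = univariate_slopes(ps)
        assert slopes["m00"] < 0 and slopes["m01"] < 0

    def test_constant_feature_warned_and_zeroed(self):
        x = np.abs(np.random.default_rng(2).standard_normal((50, 2)))
        x[:, 1] = 1.0
        ps = PairFeatureSet(features=pd.DataFrame(x, columns=["a", "flat"]),
                            labels=np.array([1, -1] * 25),
                            pair_ids=[str(i) for i in range(50)])
        with pytest.warns(UserWarning, match="flat"):
            w = univariate_weights(ps)
        assert w.mean["flat"] == 0.0


class TestRidge:
    def test_heritable_feature_dominates_coefficients(self):
        ps = _signal_pairset([0.8, 0.0, 0.0, 0.0, 0.0])
        perf, w, alpha = ridge_classify(ps, RunConfig(seed=3, **FAST))
        assert w.mean.idxmax() == "m00"
        assert perf.mean_accuracy > 0.55
        assert alpha in RunConfig().alpha_grid

    def test_shrinkage_monotone_in_alpha(self):
        ps = _signal_pairset([0.7, 0.5, 0.3, 0.0])
        norms = []
        for alpha in (0.01, 1.0, 100.0, 10000.0):
            _, w, _ = ridge_classify(
                ps, RunConfig(seed=4, n_iterations=30), alpha=alpha)
            norms.append(np.linalg.norm(w.mean.to_numpy()))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_accuracies_reproducible_from_seed(self):
        ps = _signal_pairset([0.6, 0.3, 0.0])
        cfg = RunConfig(seed=5, n_iterations=25, n_alpha_iterations=5)
        p1, w1, a1 = ridge_classify(ps, cfg)
        p2, w2, a2 = ridge_classify(ps, cfg)
        np.testing.assert_array_equal(p1.accuracies, p2.accuracies)
        pd.testing.assert_series_equal(w1.mean, w2.mean)
        assert a1 == a2

    def test_duplicated_feature_shares_weight(self):
        ps = _signal_pairset([0.8, 0.0, 0.0])
        dup = ps.features.copy()
        dup["m00_copy"] = dup["m00"]
        ps_dup = PairFeatureSet(features=dup, labels=ps.labels,
                                pair_ids=ps.pair_ids)
        _, w, _ = ridge_classify(ps_dup, RunConfig(seed=6, n_iterations=60),
                                 alpha=100.0)
        a, b = w.mean["m00"], w.mean["m00_copy"]
        assert abs(a - b) / max(a, b) < 0.10

    def test_single_feature_rejected(self):
        ps = _signal_pairset([0.5])
        with pytest.raises(MLWeightsError):
            ridge_classify(ps, RunConfig(seed=0, n_iterations=5))


class TestRandomForest:
    def test_importances_nonnegative_and_normalized(self):
        ps = _signal_pairset([0.7, 0.4, 0.0, 0.0])
        perf, w = rf_classify(ps, RunConfig(seed=7, n_iterations=25))
        assert (w.mean >= 0).all()
        # mean of per-iteration unit-sum importances still sums to 1
        assert w.mean.sum() == pytest.approx(1.0, abs=1e-10)
        assert perf.mean_auc is not None and 0.5 < perf.mean_auc <= 1.0

    def test_zero_signal_cohort_auc_at_chance(self):
        # leakage-free evaluation; averaged over cohorts because a single
        # finite null cohort carries accidental class structure (sd ~ 0.03)
        aucs = []
        for seed in (600, 601, 602):
            ps = _signal_pairset(np.zeros(6), seed=seed)
            perf, _ = rf_classify(ps, RunConfig(seed=8, n_iterations=30,
                                                strict_split=True))
            aucs.append(perf.mean_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)

    def test_oversampling_before_split_leaks(self):
        # duplicated minority rows crossing the split inflate null accuracy;
        # the strict order (split, then balance each side) removes this
        ps = _signal_pairset(np.zeros(12), seed=500)
        leaky, _, _ = ridge_classify(
            ps, RunConfig(seed=1, n_iterations=150), alpha=100.0)
        strict, _, _ = ridge_classify(
            ps, RunConfig(seed=1, n_iterations=150, strict_split=True),
            alpha=100.0)
        assert leaky.mean_accuracy > strict.mean_accuracy

    def test_variance_signal_favors_forest_over_ridge(self):
        # class difference lives in a feature's spread, not its mean:
        # trees can threshold on it twice, a linear model cannot
        rng = np.random.default_rng(9)
        n = 150
        f1 = np.concatenate([
            np.abs(rng.standard_normal(n)) * 0.25 + 0.85,   # MZ: tight band
            np.abs(rng.standard_normal(n)) * 1.8,           # DZ: wide spread
        ])
        noise = np.abs(rng.standard_normal((2 * n, 2)))
        features = pd.DataFrame(np.column_stack([f1, noise]),
                                columns=["band", "n1", "n2"])
        ps = PairFeatureSet(features=features,
                            labels=np.array([1] * n + [-1] * n),
                            pair_ids=[str(i) for i in range(2 * n)])
        cfg = RunConfig(seed=10, n_iterations=40)
        perf_rf, _ = rf_classify(ps, cfg)
        perf_ridge, _, _ = ridge_classify(ps, cfg, alpha=100.0)
        assert perf_rf.mean_accuracy > perf_ridge.mean_accuracy

    def test_duplicated_feature_splits_importance(self):
        ps = _signal_pairset([0.8] + [0.0] * 7)
        cfg = RunConfig(seed=11, n_iterations=40)
        _, w_single = rf_classify(ps, cfg)
        dup = ps.features.copy()
        dup["m00_copy"] = dup["m00"]
        ps_dup = PairFeatureSet(features=dup, labels=ps.labels, pair_ids=ps.pair_ids)
        _, w_dup = rf_classify(ps_dup, cfg)
        # the copies share the signal's importance about equally, and the
        # pair together stays on the order of the single-copy importance
        # (not doubled, as naive per-column reading would suggest)
        a, b = w_dup.mean["m00"], w_dup.mean["m00_copy"]
        assert abs(a - b) / max(a, b) < 0.2
        combined = a + b
        single = w_single.mean["m00"]
        assert 0.7 * single < combined < 1.5 * single


@pytest.fixture(scope="module")
def tune_table():
    ps = _signal_pairset([0.8, 0.7, 0.6, 0.0, 0.0, 0.0],
                         n_mz=120, n_dz=80, seed=71)
    return rf_tune(ps, n_trees_grid=(20, 60, 100, 140),
                   max_depth_grid=(1, 5, None),
                   max_features_grid=("sqrt", "log2", None),
                   n_reps=20, seed=0)


class TestRFTune:
    def test_oob_rises_then_plateaus_in_n_trees(self, tune_table):
        sub = tune_table[(tune_table.max_depth == 5)
                         & (tune_table.max_features == "sqrt")]
        by_trees = sub.set_index("n_trees").oob_accuracy
        assert by_trees[140] >= by_trees[20] - 0.02
        assert abs(by_trees[140] - by_trees[100]) < 0.03  # plateau

    def test_all_features_option_worst(self, tune_table):
        means = tune_table.groupby("max_features").oob_accuracy.mean()
        assert means["all"] <= means[["sqrt", "log2"]].min() + 0.01

    def test_depth_one_underfits(self, tune_table):
        sub = tune_table[(tune_table.n_trees == 100)
                         & (tune_table.max_features == "sqrt")]
        by_depth = sub.set_index("max_depth").oob_accuracy
        assert by_depth[1] < by_depth[5]

    def test_too_few_pairs_rejected(self):
        ps = _signal_pairset([0.5, 0.5], n_mz=5, n_dz=5)
        with pytest.raises(MLWeightsError):
            rf_tune(ps)


class TestHaufe:
    def test_identity_covariance_preserves_weights(self):
        w = np.array([0.5, -1.0, 2.0])
        np.testing.assert_allclose(haufe_transform(w, np.eye(3)), w)

    def test_two_feature_closed_form(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(haufe_transform([1.0, 0.0], cov), [1.0, 0.5])

    def test_suppressor_feature_deflated(self):
        # f1 = signal + shared noise, f2 = shared noise only; the optimal
        # decoder weights f2 strongly (to cancel noise) but its forward-model
        # activation is much smaller than f1's
        rng = np.random.default_rng(12)
        n = 5000
        s = rng.standard_normal(n)
        shared = rng.standard_normal(n)
        x = np.column_stack([s + shared, shared])
        w = np.linalg.solve(x.T @ x / n, x.T @ s / n)  # OLS decoder for s
        pattern = haufe_transform(w, np.cov(x.T))
        assert abs(w[1]) > 0.5 * abs(w[0])          # suppressor weight is large
        assert abs(pattern[1]) < 0.2 * abs(pattern[0])

    def test_dimension_mismatch(self):
        with pytest.raises(MLWeightsError):
            haufe_transform(np.ones(3), np.eye(4))


def test_weight_rankings_track_true_heritability():
    """All three weight profiles rank measures consistently with planted a2."""
    from scipy.stats import spearmanr
    a2 = np.linspace(0.0, 0.8, 9)
    ps = _signal_pairset(a2, n_mz=400, n_dz=300, seed=73)
    uni = univariate_weights(ps).mean.to_numpy()
    _, ridge_w, _ = ridge_classify(ps, RunConfig(seed=13, n_iterations=50),
                                   alpha=100.0)
    _, rf_w = rf_classify(ps, RunConfig(seed=13, n_iterations=30))
    for weights in (uni, ridge_w.mean.to_numpy(), rf_w.mean.to_numpy()):
        assert spearmanr(a2, weights).statistic >= 0.7
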