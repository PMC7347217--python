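"""Standardization, residualization, inverse-normal transform, and the
pair-difference feature construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from twinherit import build_pair_features, inverse_normal_transform, oversample_balance, zscore
from twinherit.preprocess import (
    PairFeatureSet,
    PreprocessError,
    covariate_design,
    inverse_normal_transform_frame,
    residualize,
)


class TestZscore:
    def test_basic_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = zscore(df)
        sd = np.std([1, 2, 3])
        np.testing.assert_allclose(z["a"], np.array([-1.0, 0.0, 1.0]) / sd)

    def test_zero_mean_unit_sd(self, tiny_cohort):
        z = zscore(tiny_cohort.phenotypes)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_idempotent(self, tiny_cohort):
        z = zscore(tiny_cohort.phenotypes)
        pd.testing.assert_frame_equal(zscore(z), z, atol=1e-12, rtol=0)

    def test_constant_column_error_names_measure(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(PreprocessError, match="flat"):
            zscore(df)


class TestResidualize:
    def test_removes_linear_age_effect(self):
        rng = np.random.default_rng(0)
        n = 1000
        age = rng.uniform(22, 36, n)
        sex = rng.integers(0, 2, n).astype(float)
        pheno = pd.DataFrame({"m": 2.0 * age + rng.standard_normal(n)})
        resid = residualize(pheno, age, sex)
        assert abs(np.corrcoef(resid["m"], age)[0, 1]) < 0.01

    def test_no_covariate_effect_recovers_centered_phenotype(self):
        rng = np.random.default_rng(1)
        n = 400
        age = rng.uniform(22, 36, n)
        sex = rng.integers(0, 2, n).astype(float)
        pheno = pd.DataFrame({"m": rng.standard_normal(n)})
        resid = residualize(pheno, age, sex)
        # residuals are centered and barely perturbed when covariates are noise
        assert abs(resid["m"].mean()) < 1e-10
        assert np.corrcoef(resid["m"], pheno["m"] - pheno["m"].mean())[0, 1] > 0.98

    def test_single_sex_cohort_is_collinear(self):
        rng = np.random.default_rng(2)
        n = 50
        age = rng.uniform(22, 36, n)
        sex = np.zeros(n)
        pheno = pd.DataFrame({"m": rng.standard_normal(n)})
        with pytest.raises(PreprocessError, match="collinear"):
            residualize(pheno, age, sex)

    def test_design_columns(self):
        d = covariate_design(np.array([30.0]), np.array([1.0]))
        assert list(d.columns) == ["intercept", "age", "sex", "age_x_sex",
                                   "age2", "age2_x_sex"]
        np.testing.assert_allclose(d.iloc[0], [1, 30, 1, 30, 900, 900])


class TestInverseNormalTransform:
    def test_blom_n3_frozen_values(self):
        # Phi^-1 of (1-3/8)/3.25, (2-3/8)/3.25, (3-3/8)/3.25
        out = inverse_normal_transform(np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out, [-0.8694, 0.0, 0.8694], atol=1e-3)

    def test_median_of_odd_tiefree_sample_is_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(101)
        out = inverse_normal_transform(x)
        assert out[np.argsort(x)[50]] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_and_symmetric(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=200)  # deliberately skewed input
        out = inverse_normal_transform(x)
        assert np.all(np.diff(out[np.argsort(x)]) > 0)
        from scipy.stats import skew
        assert abs(skew(out)) < 1e-6

    def test_ties_get_average_rank(self):
        out = inverse_normal_transform(np.array([1.0, 2.0, 2.0, 3.0]))
        assert out[1] == out[2]

    def test_too_few_distinct_values(self):
        with pytest.raises(PreprocessError):
            inverse_normal_transform(np.array([1.0, 1.0, 2.0, 2.0]))

    def test_frame_wrapper_preserves_shape(self, tiny_cohort):
        out = inverse_normal_transform_frame(tiny_cohort.phenotypes)
        assert out.shape == tiny_cohort.phenotypes.shape


class TestPairFeatures:
    def test_row_count_and_labels(self, small_cohort):
        ps = build_pair_features(small_cohort)
        assert len(ps.features) == 150 + 90
        assert ps.n_mz == 150 and ps.n_dz == 90
        assert set(np.unique(ps.labels)) == {-1, 1}
        assert (ps.features.to_numpy() >= 0).all()

    def test_invariant_to_within_pair_order(self, tiny_cohort):
        ps = build_pair_features(tiny_cohort)
        # swapping twin order only flips the sign inside the absolute value
        z = zscore(tiny_cohort.phenotypes)
        t1, t2 = tiny_cohort.twin_pairs("MZ")[0]
        row = np.abs(z.loc[t2].to_numpy() - z.loc[t1].to_numpy())
        np.testing.assert_allclose(ps.features.iloc[0].to_numpy(), row)

    def test_missing_zygosity_errors(self, tiny_cohort):
        only_mz = tiny_cohort.subjects[tiny_cohort.subjects.zygosity != "DZ"]
        import copy
        cohort = copy.copy(tiny_cohort)
        cohort.subjects = only_mz
        with pytest.raises(PreprocessError, match="DZ"):
            build_pair_features(cohort)


class TestOversampleBalance:
    def _pairset(self, n_mz, n_dz, seed=0):
        rng = np.random.default_rng(seed)
        n = n_mz + n_dz
        return PairFeatureSet(
            features=pd.DataFrame(np.abs(rng.standard_normal((n, 3))),
                                  columns=list("abc")),
            labels=np.array([1] * n_mz + [-1] * n_dz),
            pair_ids=[f"p{i}" for i in range(n)],
        )

    def test_minority_raised_to_majority(self):
        ps = self._pairset(149, 90)
        out = oversample_balance(ps, 0)
        assert out.n_mz == 149 and out.n_dz == 149

    def test_majority_multiset_untouched(self):
        ps = self._pairset(20, 7)
        out = oversample_balance(ps, 1)
        maj_in = ps.features[ps.labels == 1].to_numpy()
        maj_out = out.features[out.labels == 1].to_numpy()
        np.testing.assert_array_equal(np.sort(maj_in, axis=0),
                                      np.sort(maj_out, axis=0))

    def test_already_balanced_returned_unchanged(self):
        ps = self._pairset(10, 10)
        out = oversample_balance(ps, 2)
        pd.testing.assert_frame_equal(out.features, ps.features)

    def test_single_minority_row_repeated(self):
        ps = self._pairset(3, 1)
        out = oversample_balance(ps, 3)
        dz = out.features[out.labels == -1].to_numpy()
        assert dz.shape[0] == 3
        assert (dz == dz[0]).all()

    def test_reproducible_from_seed(self):
        ps = self._pairset(30, 11)
        a = oversample_balance(ps, 5)
        b = oversample_balance(ps, 5)
        pd.testing.assert_frame_equal(a.features, b.features)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n_mz=hst.integers(1, 25), n_dz=hst.integers(1, 25),
           seed=hst.integers(0, 10))
    def test_balancing_property(self, n_mz, n_dz, seed):
        ps = self._pairset(n_mz, n_dz, seed=seed)
        out = oversample_balance(ps, seed)
        assert out.n_mz == out.n_dz == max(n_mz, n_dz)
        # minority output rows all come from minority input rows
        minority = 1 if n_mz < n_dz else -1
        if n_mz != n_dz:
            pool = {tuple(r) for r in ps.features[ps.labels == minority].to_numpy()}
            assert all(tuple(r) in pool
                       for r in out.features[out.labels == minority].to_numpy())
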