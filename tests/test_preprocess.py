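"""Cleaning chain: missingness filters, log transform, imputation, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ganfe
from ganfe import preprocess as pp
from ganfe.cohort import Cohort, FeatureMeta


def _cohort(X, y=None, kinds=None):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    kinds = kinds or ["metabolite"] * p
    meta = [FeatureMeta(f"f{j}", kinds[j]) for j in range(p)]
    y = np.zeros(n, dtype=int) if y is None else np.asarray(y)
    ids = np.array([f"r{i}" for i in range(n)])
    return Cohort(ids, X, y, meta)


class TestMetaboliteFilter:
    def test_boundary_strictly_greater_than_threshold(self):
        X = np.ones((20, 3))
        X[:5, 0] = np.nan   # 25% missing -> removed
        X[:4, 1] = np.nan   # exactly 20% -> retained
        out = pp.filter_metabolites_by_missingness(_cohort(X), 0.20)
        assert out.feature_names == ["f1", "f2"]

    def test_clinical_columns_never_removed(self):
        X = np.ones((10, 2))
        X[:9, 0] = np.nan
        cohort = _cohort(X, kinds=["clinical-continuous", "metabolite"])
        out = pp.filter_metabolites_by_missingness(cohort, 0.20)
        assert out.feature_names == ["f0", "f1"]

    def test_fully_observed_unchanged(self, small_cohort):
        out = pp.filter_metabolites_by_missingness(small_cohort)
        np.testing.assert_array_equal(out.X, small_cohort.X)


class TestParticipantFilter:
    def test_boundary_over_threshold(self):
        X = np.ones((4, 20))
        X[0, :3] = np.nan   # 15% -> removed
        X[1, :2] = np.nan   # exactly 10% -> retained
        out = pp.filter_participants_by_missingness(_cohort(X), 0.10)
        assert out.ids.tolist() == ["r1", "r2", "r3"]

    def test_planted_overthreshold_rows_all_removed(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(size=(50, 30))
        bad = rng.choice(50, size=10, replace=False)
        for r in bad:
            X[r, rng.choice(30, size=6, replace=False)] = np.nan  # 20%
        out = pp.filter_participants_by_missingness(_cohort(X), 0.10)
        assert out.n == 40
        assert not set(f"r{i}" for i in bad) & set(out.ids.tolist())

    def test_labels_filtered_in_lockstep(self):
        X = np.ones((3, 10))
        X[1, :5] = np.nan
        cohort = _cohort(X, y=[0, 1, 0])
        out = pp.filter_participants_by_missingness(cohort, 0.10)
        assert out.y.tolist() == [0, 0]


class TestFilterProperties:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_filters_commute_with_permutation(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(size=(25, 12))
        X[rng.random(X.shape) < 0.25] = np.nan
        cohort = _cohort(X)
        perm_rows = rng.permutation(25)
        perm_cols = rng.permutation(12)
        direct = pp.filter_participants_by_missingness(
            pp.filter_metabolites_by_missingness(cohort))
        permuted = pp.filter_participants_by_missingness(
            pp.filter_metabolites_by_missingness(
                cohort.take_rows(perm_rows).take_columns(perm_cols)))
        assert set(direct.ids.tolist()) == set(permuted.ids.tolist())
        assert set(direct.feature_names) == set(permuted.feature_names)


class TestLogTransform:
    def test_value_e_maps_to_one_and_clinical_untouched(self):
        X = np.array([[5.0, np.e], [7.0, np.e ** 2]])
        cohort = _cohort(X, kinds=["clinical-continuous", "metabolite"])
        out = pp.log_transform_metabolites(cohort)
        np.testing.assert_allclose(out.X[:, 1], [1.0, 2.0])
        np.testing.assert_allclose(out.X[:, 0], [5.0, 7.0])

    def test_lognormal_column_symmetric_after_transform(self):
        rng = np.random.default_rng(1)
        X = np.exp(rng.normal(0, 1, size=(4000, 1)))
        out = pp.log_transform_metabolites(_cohort(X))
        assert abs(stats.skew(out.X[:, 0])) < 0.15

    def test_nonpositive_value_names_row_and_column(self):
        X = np.array([[1.0, 2.0], [1.0, -3.0]])
        with pytest.raises(ValueError, match="r1.*f1"):
            pp.log_transform_metabolites(_cohort(X))

    def test_missing_cells_stay_missing(self):
        X = np.array([[1.0, np.nan], [2.0, 4.0]])
        out = pp.log_transform_metabolites(_cohort(X))
        assert np.isnan(out.X[0, 1])


class TestChainedImputation:
    def test_complete_matrix_unchanged(self, small_cohort):
        out = pp.impute_chained(small_cohort, seed=0)
        np.testing.assert_array_equal(out.X, small_cohort.X)

    def test_perfectly_correlated_partner_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        X = np.column_stack([a, a.copy()])
        X[7, 1] = np.nan
        out = pp.impute_chained(_cohort(X), seed=0)
        assert abs(out.X[7, 1] - a[7]) < 1e-6

    def test_beats_mean_imputation_on_correlated_mcar(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(300, 1))
        truth = z + 0.3 * rng.normal(size=(300, 5))
        X = truth.copy()
        holes = rng.random(X.shape) < 0.10
        holes[:, 0] = False  # keep one fully observed feature
        X[holes] = np.nan
        out = pp.impute_chained(_cohort(X), seed=0)
        rmse = np.sqrt(np.mean((out.X[holes] - truth[holes]) ** 2))
        col_means = np.nanmean(X, axis=0)
        mean_fill = np.where(holes, col_means, X)
        rmse_mean = np.sqrt(np.mean((mean_fill[holes] - truth[holes]) ** 2))
        assert rmse < rmse_mean

    def test_all_missing_feature_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="no observed values"):
            pp.impute_chained(_cohort(X))


class TestMinMax:
    def test_basic_mapping(self):
        cohort = _cohort(np.array([[2.0], [4.0], [6.0]]))
        scaler = pp.minmax_fit(cohort)
        out = pp.minmax_apply(scaler, cohort)
        np.testing.assert_allclose(out.X[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        cohort = _cohort(np.full((4, 1), 3.3))
        out = pp.minmax_apply(pp.minmax_fit(cohort), cohort)
        np.testing.assert_array_equal(out.X, np.zeros((4, 1)))

    def test_out_of_range_clipped(self):
        fit = _cohort(np.array([[2.0], [6.0]]))
        scaler = pp.minmax_fit(fit)
        out = pp.minmax_apply(scaler, _cohort(np.array([[8.0], [0.0]])))
        np.testing.assert_allclose(out.X[:, 0], [1.0, 0.0])

    def test_feature_mismatch_rejected(self):
        scaler = pp.minmax_fit(_cohort(np.ones((2, 1))))
        two = _cohort(np.ones((2, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            pp.minmax_apply(scaler, two)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_range_and_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 10, size=(12, 4))
        cohort = _cohort(X)
        scaler = pp.minmax_fit(cohort)
        out = pp.minmax_apply(scaler, cohort)
        assert (out.X >= 0).all() and (out.X <= 1).all()
        np.testing.assert_allclose(scaler.inverse(out.X), X, atol=1e-9)

    def test_json_round_trip(self, tmp_path):
        scaler = pp.minmax_fit(_cohort(np.array([[1.0, -2.0], [3.0, 5.0]])))
        path = tmp_path / "scaler.json"
        scaler.to_json(path)
        back = pp.Scaler.from_json(path)
        np.testing.assert_allclose(back.mins, scaler.mins)
        np.testing.assert_allclose(back.maxs, scaler.maxs)
        assert back.feature_names == scaler.feature_names
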