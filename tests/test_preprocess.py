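"""Cleaning chain: missingness and SD filters, kNN imputation,
standardization, and the fixed stage order."""

import numpy as np
import pytest

from modmix.preprocess import (
    PreprocessConfig,
    PreprocessReport,
    filter_low_variance,
    filter_missing,
    knn_impute,
    preprocess,
    standardize,
)

from conftest import make_matrix


class TestFilterMissing:
    def test_boundary_at_threshold(self):
        # 1 of 10 missing (exactly 10%) is kept; 2 of 10 (20%) is removed
        values = np.ones((2, 10))
        values[0, 0] = np.nan
        values[1, :2] = np.nan
        out = filter_missing(make_matrix(values), 0.10)
        assert out.feature_ids == ["f1"]

    def test_counts_on_toy(self):
        values = np.random.default_rng(0).random((6, 10))
        for i, nmiss in enumerate([0, 1, 1, 2, 3, 0]):
            values[i, :nmiss] = np.nan
        out = filter_missing(make_matrix(values), 0.10)
        assert out.n_features == 4

    def test_all_removed_is_error(self):
        values = np.full((2, 4), np.nan)
        values[:, 0] = 1.0
        with pytest.raises(ValueError, match="relax"):
            filter_missing(make_matrix(values), 0.10)


class TestFilterLowVariance:
    def test_percentile_threshold_interpolated(self):
        # SDs 1,2,3,4 -> 25th percentile 1.75 (linear interpolation);
        # only the SD-1 feature falls strictly below
        rng = np.random.default_rng(1)
        base = rng.standard_normal(50)
        base = (base - base.mean()) / base.std(ddof=1)
        values = np.vstack([sd * base for sd in (1.0, 2.0, 3.0, 4.0)])
        sds = values.std(axis=1, ddof=1)
        np.testing.assert_allclose(np.percentile(sds, 25), 1.75, atol=1e-12)
        out = filter_low_variance(make_matrix(values), 25)
        assert out.feature_ids == ["f2", "f3", "f4"]

    def test_identical_sds_nothing_removed(self):
        values = np.vstack([np.array([1.0, 2.0, 3.0])] * 4)
        out = filter_low_variance(make_matrix(values), 25)
        assert out.n_features == 4

    def test_percentile_zero_keeps_all(self):
        values = np.random.default_rng(2).random((5, 6))
        assert filter_low_variance(make_matrix(values), 0).n_features == 5


class TestKnnImpute:
    def test_no_missing_identity(self):
        values = np.random.default_rng(3).random((4, 5))
        out, n = knn_impute(make_matrix(values), 2)
        assert n == 0
        np.testing.assert_array_equal(out.values, values)

    def test_nearest_neighbour_value(self):
        # f3 missing at s1; over the shared samples f1 is far closer than f2
        values = np.array([
            [2.0, 1.0, 1.0],
            [10.0, 8.0, 9.0],
            [np.nan, 1.1, 0.9],
        ])
        out, n = knn_impute(make_matrix(values), 1)
        assert n == 1
        assert out.values[2, 0] == 2.0
        # observed cells untouched
        np.testing.assert_array_equal(out.values[:2], values[:2])

    def test_k_clamped_to_available(self):
        values = np.array([
            [1.0, 2.0, 3.0],
            [2.0, 3.0, 4.0],
            [np.nan, 2.5, 3.5],
        ])
        out, _ = knn_impute(make_matrix(values), 99)
        assert out.values[2, 0] == pytest.approx(1.5)  # mean of both neighbours

    def test_fallback_to_feature_mean(self):
        # neighbours unobserved at s1 -> feature mean fallback
        values = np.array([
            [np.nan, 4.0, 8.0],
            [np.nan, 1.0, 1.0],
        ])
        out, _ = knn_impute(make_matrix(values), 1)
        assert out.values[0, 0] == pytest.approx(6.0)


class TestStandardize:
    def test_closed_form(self):
        out = standardize(make_matrix([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]], atol=1e-12)

    def test_idempotent_and_moments(self):
        values = np.random.default_rng(4).standard_normal((50, 20)) * 3 + 1
        once = standardize(make_matrix(values))
        assert np.abs(once.values.mean(axis=1)).max() < 1e-10
        np.testing.assert_allclose(once.values.std(axis=1, ddof=1), 1.0, atol=1e-10)
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_zero_sd_error_names_feature(self):
        values = np.vstack([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="f2"):
            standardize(make_matrix(values))


class TestPreprocessPipeline:
    def test_clean_matrix_default_keeps_75_of_100(self):
        rng = np.random.default_rng(5)
        # distinct per-feature scales so the SD order is unambiguous
        scales = np.linspace(0.5, 5.0, 100)
        values = rng.standard_normal((100, 20)) * scales[:, None]
        out, report = preprocess(make_matrix(values), PreprocessConfig())
        assert out.n_features == 75
        assert report.n_removed_low_sd == 25
        assert report.n_removed_missing == 0

    def test_feature_cap(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal((300, 10)) * rng.uniform(0.5, 2.0, 300)[:, None]
        out, report = preprocess(make_matrix(values),
                                 PreprocessConfig(sd_percentile=0, max_features=100))
        assert out.n_features == 100
        assert report.n_removed_cap == 200

    def test_output_complete_and_standardized(self):
        rng = np.random.default_rng(7)
        values = rng.standard_normal((40, 30)) * rng.uniform(0.5, 3.0, 40)[:, None]
        miss = rng.random(values.shape) < 0.05
        values[miss] = np.nan
        out, report = preprocess(make_matrix(values), PreprocessConfig())
        assert not np.isnan(out.values).any()
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0, atol=1e-10)
        assert report.n_imputed_cells > 0

    def test_report_conservation(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((30, 12)) * rng.uniform(0.5, 2.0, 30)[:, None]
        values[rng.random(values.shape) < 0.08] = np.nan
        _, r = preprocess(make_matrix(values), PreprocessConfig())
        assert (r.n_features_in - r.n_removed_missing - r.n_removed_low_sd
                - r.n_removed_cap) == r.n_features_out

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal((30, 15)) * rng.uniform(0.5, 2.0, 30)[:, None]
        values[rng.random(values.shape) < 0.05] = np.nan
        a, _ = preprocess(make_matrix(values.copy()), PreprocessConfig())
        b, _ = preprocess(make_matrix(values.copy()), PreprocessConfig())
        np.testing.assert_array_equal(a.values, b.values)

    def test_stage_order_visible_in_report(self):
        # a feature that is low-SD *and* too missing is charged to the
        # missingness stage, which runs first
        rng = np.random.default_rng(10)
        values = rng.standard_normal((10, 10)) * np.linspace(1, 2, 10)[:, None]
        values[0] *= 0.01          # lowest SD by far
        values[0, :5] = np.nan     # and 50% missing
        _, r = preprocess(make_matrix(values), PreprocessConfig())
        assert r.n_removed_missing == 1

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PreprocessConfig(max_missing_frac=1.5)
        with pytest.raises(ValueError):
            PreprocessReport(10, 1, 1, 0, 9, 0)
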