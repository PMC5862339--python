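"""Normalization methods: MA core, distribution matching, regression, loess."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from protnorm.io_model import AbundanceMatrix, ProtNormError
from protnorm.normalization import (
    LoessNormalizer,
    MedianNormalizer,
    ProgenesisNormalizer,
    QuantileNormalizer,
    RlrNormalizer,
    ma_transform,
    normalize_linreg,
    normalize_loess,
    normalize_median,
    normalize_progenesis,
    normalize_quantile,
)
from protnorm.synthetic import BiasRecord

from conftest import make_log2_matrix


class TestMATransform:
    def test_pairwise_definition(self):
        ma = ma_transform(np.array([3.0, 5.0]), np.array([1.0, 3.0]), pairwise=True)
        np.testing.assert_array_equal(ma.A, [2.0, 4.0])
        np.testing.assert_array_equal(ma.M, [2.0, 2.0])

    def test_identical_vectors_give_zero_m(self):
        x = np.array([1.0, 2.0, 3.0])
        ma = ma_transform(x, x)
        np.testing.assert_array_equal(ma.M, np.zeros(3))

    def test_missing_propagates_to_both(self):
        ma = ma_transform(np.array([1.0, 2.0]), np.array([np.nan, 3.0]))
        assert np.isnan(ma.A[0]) and np.isnan(ma.M[0])
        assert not np.isnan(ma.M[1])

    def test_global_mode_uses_reference_as_a(self):
        ma = ma_transform(np.array([3.0]), np.array([1.0]), pairwise=False)
        assert ma.A[0] == 1.0 and ma.M[0] == 2.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ProtNormError):
            ma_transform(np.ones(3), np.ones(2))


class TestMedian:
    def test_two_column_example(self):
        m = make_log2_matrix(np.array([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]]))
        out = normalize_median(m).matrix.values
        np.testing.assert_allclose(out[:, 0], [2.0, 3.0, 4.0])
        np.testing.assert_allclose(out[:, 1], [2.0, 3.0, 4.0])

    def test_equal_medians_unchanged(self):
        m = make_log2_matrix(np.array([[1.0, 0.0], [2.0, 2.0], [3.0, 4.0]]))
        out = normalize_median(m).matrix.values
        np.testing.assert_allclose(out, m.values)

    def test_random_matrix_medians_equal_target(self):
        rng = np.random.default_rng(1)
        m = make_log2_matrix(rng.normal(20, 2, size=(101, 5)))
        res = normalize_median(m)
        medians = np.nanmedian(res.matrix.values, axis=0)
        target = np.nanmedian(m.values, axis=0).mean()
        np.testing.assert_allclose(medians, target, atol=1e-9)

    def test_all_missing_sample_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ProtNormError):
            normalize_median(make_log2_matrix(vals))


class TestQuantile:
    def test_mean_of_order_statistics(self):
        m = make_log2_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = normalize_quantile(m).matrix.values
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([5.0, 1.0, 3.0, 2.0])
        m = make_log2_matrix(np.column_stack([col, col, col]))
        out = normalize_quantile(m).matrix.values
        np.testing.assert_allclose(out, m.values)

    def test_ties_match_explicit_sort_average_unsort_oracle(self):
        # column 0 has a tie at value 2; oracle does the rank bookkeeping
        # by hand: sort each column, average across columns per rank,
        # unsort, then average reference values over tied entries
        V = np.array([[2.0, 7.0, 1.0],
                      [2.0, 5.0, 2.0],
                      [1.0, 6.0, 4.0],
                      [4.0, 8.0, 3.0]])
        ref = np.mean([np.sort(V[:, j]) for j in range(3)], axis=0)
        expected = np.empty_like(V)
        for j in range(3):
            order = np.argsort(V[:, j], kind="stable")
            col = np.empty(4)
            col[order] = ref
            for val in np.unique(V[:, j]):
                sel = V[:, j] == val
                col[sel] = col[sel].mean()
            expected[:, j] = col
        out = normalize_quantile(make_log2_matrix(V)).matrix.values
        np.testing.assert_allclose(out, expected)

    def test_complete_columns_share_sorted_values_exactly(self):
        rng = np.random.default_rng(2)
        m = make_log2_matrix(rng.normal(20, 2, size=(200, 6)))
        out = normalize_quantile(m).matrix.values
        first = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_array_equal(np.sort(out[:, j]), first)

    def test_missing_values_stay_missing(self):
        V = np.array([[1.0, 4.0], [np.nan, 5.0], [3.0, 6.0], [2.0, 7.0]])
        out = normalize_quantile(make_log2_matrix(V)).matrix.values
        assert np.isnan(out[1, 0])
        assert np.isnan(out).sum() == 1


class TestRlr:
    def test_affine_bias_recovered_exactly_on_noiseless_data(self):
        # oracle: exact least squares on noiseless data recovers (a, b)
        rng = np.random.default_rng(3)
        x = rng.normal(20, 2.5, 500)
        a_true, b_true = 0.7, 1.2
        # reference (median sample) must equal the clean profile: mirror
        # the bias so the pointwise median is the identity
        V = np.column_stack([x, a_true + b_true * x, -a_true + (2 - b_true) * x])
        m = make_log2_matrix(V)
        res = normalize_linreg(m, variant="rlr")
        np.testing.assert_allclose(res.matrix.values[:, 1], x, atol=1e-6)
        a_fit, b_fit = res.diagnostics["coefficients"][1]
        assert abs(a_fit - a_true) < 1e-6 and abs(b_fit - b_true) < 1e-6

    def test_rlr_ma_removes_constant_offset(self):
        rng = np.random.default_rng(4)
        x = rng.normal(20, 2.5, 300)
        V = np.column_stack([x, x + 2.0, x - 2.0])
        res = normalize_linreg(make_log2_matrix(V), variant="rlr_ma")
        np.testing.assert_allclose(res.matrix.values[:, 1], x, atol=1e-8)

    @pytest.mark.parametrize("variant", ["rlr", "rlr_ma", "rlr_ma_cyclic"])
    def test_identical_samples_unchanged(self, variant):
        rng = np.random.default_rng(5)
        x = rng.normal(20, 2.5, 100)
        m = make_log2_matrix(np.column_stack([x, x]))
        res = normalize_linreg(m, variant=variant)
        np.testing.assert_allclose(res.matrix.values, m.values, atol=1e-8)

    def test_too_few_complete_proteins_rejected(self):
        m = make_log2_matrix(np.array([[1.0, 2.0], [2.0, 3.0]]))
        with pytest.raises(ProtNormError):
            normalize_linreg(m, variant="rlr")

    def test_robustness_against_outliers(self):
        # a handful of spiked proteins must not tilt the fitted line
        rng = np.random.default_rng(6)
        x = rng.normal(20, 2.5, 1000)
        y = 0.5 + x.copy()
        y[:20] += 4.0  # strong outliers
        V = np.column_stack([x, y, x])
        res = normalize_linreg(make_log2_matrix(V), variant="rlr_ma")
        a, b = res.diagnostics["coefficients"][1]
        assert abs(a - 0.5) < 0.15 and abs(b) < 0.02


class TestLoess:
    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(7)
        x = rng.normal(20, 2.5, 200)
        m = make_log2_matrix(np.column_stack([x, x]))
        res = normalize_loess(m, variant="fast_ref")
        np.testing.assert_allclose(res.matrix.values, m.values, atol=1e-8)

    def test_constant_offset_reduces_to_median_like_shift(self):
        rng = np.random.default_rng(8)
        x = rng.normal(20, 2.5, 400)
        V = np.column_stack([x + 1.0, x - 1.0])
        res = normalize_loess(make_log2_matrix(V), variant="fast_ref")
        out = res.matrix.values
        # residual offset between samples < 1e-3
        assert np.abs(out[:, 0] - out[:, 1]).max() < 1e-3

    def test_injected_smooth_trend_removed(self):
        # known-curve oracle: cubic bias from the generator's bias model,
        # mean |deviation from clean| must drop by >= 90 %
        rng = np.random.default_rng(9)
        x = rng.normal(20, 2.5, 1000)
        clean = np.tile(x[:, None], (1, 4))
        c = np.array([0.35, 0.12, -0.04])
        z = np.linspace(-2.5, 2.5, 101)
        c *= 0.5 / np.max(np.abs(c[0] * z + c[1] * z**2 + c[2] * z**3))
        coefs = np.zeros((4, 3))
        coefs[1] = c
        coefs[2] = -c
        rec = BiasRecord(kind="smooth_nonlinear", cubic_coefs=coefs,
                         x_center=20.0, x_scale=2.5)
        biased = rec.apply(clean)
        res = normalize_loess(make_log2_matrix(biased), variant="fast_ref")
        before = np.mean(np.abs(biased - clean))
        after = np.mean(np.abs(res.matrix.values - clean))
        assert after < 0.1 * before

    def test_cyclic_variant_aligns_pair(self):
        rng = np.random.default_rng(10)
        x = rng.normal(20, 2.5, 500)
        V = np.column_stack([x + 0.5, x - 0.5])
        res = normalize_loess(make_log2_matrix(V), variant="cyclic")
        out = res.matrix.values
        assert np.abs(out[:, 0] - out[:, 1]).max() < 1e-3

    def test_insufficient_points_rejected(self):
        m = make_log2_matrix(np.random.default_rng(0).normal(20, 1, (10, 2)))
        with pytest.raises(ProtNormError):
            normalize_loess(m, variant="fast_ref")


class TestProgenesis:
    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(11)
        x = rng.normal(20, 2.5, 200)
        V = np.column_stack([x, x - 1.0])
        res = normalize_progenesis(make_log2_matrix(V), reference=0)
        np.testing.assert_allclose(res.matrix.values[:, 1], x, atol=1e-9)
        assert res.diagnostics["shift"][1] == pytest.approx(1.0)

    def test_reference_unchanged(self):
        rng = np.random.default_rng(12)
        x = rng.normal(20, 2.5, 100)
        V = np.column_stack([x, x + 3.0])
        res = normalize_progenesis(make_log2_matrix(V), reference=0)
        np.testing.assert_array_equal(res.matrix.values[:, 0], x)

    def test_auto_reference_and_shift_recovery(self):
        # sample with highest mean pairwise correlation becomes reference;
        # injected offsets are recovered within 0.01
        rng = np.random.default_rng(13)
        x = rng.normal(20, 2.5, 2000)
        noise = rng.normal(0, 0.05, (2000, 4))
        noise[:, 2] = rng.normal(0, 0.15, 2000)  # sample 2 is the noisy outlier
        offsets = np.array([0.5, -0.3, 0.2, 0.0])
        V = x[:, None] + offsets[None, :] + noise
        res = normalize_progenesis(make_log2_matrix(V), reference="auto")
        ref = res.diagnostics["reference_index"]
        assert ref != 2
        shifts = res.diagnostics["shift"]
        rel = -(offsets - offsets[ref])
        np.testing.assert_allclose(shifts, rel, atol=0.01)


class TestEstimatorAPI:
    @pytest.mark.parametrize("est", [
        MedianNormalizer(),
        QuantileNormalizer(),
        RlrNormalizer(variant="rlr_ma"),
        LoessNormalizer(variant="fast_ref"),
        ProgenesisNormalizer(),
    ])
    def test_clone_fit_transform_shapes_and_missing(self, est):
        rng = np.random.default_rng(14)
        X = rng.normal(20, 2, size=(4, 120))  # runs × proteins
        X[0, 5] = np.nan
        est = clone(est)
        out = est.fit(X).transform(X)
        assert out.shape == X.shape
        assert np.isnan(out[0, 5])
        assert hasattr(est, "diagnostics_")

    def test_get_set_params_round_trip(self):
        est = LoessNormalizer(variant="cyclic", frac=0.5)
        params = est.get_params()
        assert params["variant"] == "cyclic" and params["frac"] == 0.5
        est.set_params(frac=0.9)
        assert est.frac == 0.9

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_shift_methods_preserve_missing_and_shape(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.normal(20, 2, size=(30, 3))
        V[rng.random(V.shape) < 0.1] = np.nan
        if np.isnan(V).all(axis=0).any():
            return
        m = make_log2_matrix(V)
        out = normalize_median(m).matrix
        assert out.values.shape == V.shape
        np.testing.assert_array_equal(np.isnan(out.values), np.isnan(V))
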