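"""Differential expression statistics, ROC/AUC, and DeLong's test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from protnorm.diffexpr import (
    _rots_stat,
    delong_test,
    roc_auc,
    rots_test,
    t_test_two_group,
)
from protnorm.io_model import ProtNormError, StudyDesign

from conftest import make_log2_matrix


DESIGN_33 = StudyDesign(groups={"s0": "A", "s1": "A", "s2": "A",
                                "s3": "B", "s4": "B", "s5": "B"})


class TestWelch:
    def test_identical_groups_give_zero_t_and_p_one(self):
        row = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        m = make_log2_matrix(row[None, :])
        res = t_test_two_group(m, DESIGN_33, "A", "B")
        assert res.table["statistic"].iloc[0] == pytest.approx(0.0)
        assert res.table["p_or_fdr"].iloc[0] == pytest.approx(1.0)

    def test_matches_hand_computed_welch_value(self):
        # groups [1,2,3] vs [2,3,4]: means 2,3, variances 1,1 =>
        # t = 1 / sqrt(1/3 + 1/3) = 1.224745, df = 4
        row = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
        m = make_log2_matrix(row[None, :])
        res = t_test_two_group(m, DESIGN_33, "A", "B")
        assert res.table["statistic"].iloc[0] == pytest.approx(np.sqrt(1.5))
        expected_p = 2 * stats.t.sf(np.sqrt(1.5), 4)
        assert res.table["p_or_fdr"].iloc[0] == pytest.approx(expected_p)
        assert res.table["logfc"].iloc[0] == pytest.approx(1.0)

    def test_zero_over_zero_becomes_missing(self):
        row = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        m = make_log2_matrix(row[None, :])
        res = t_test_two_group(m, DESIGN_33, "A", "B")
        assert np.isnan(res.table["statistic"].iloc[0])

    def test_insufficient_observations_become_missing(self):
        row = np.array([1.0, np.nan, np.nan, 2.0, 3.0, 4.0])
        m = make_log2_matrix(row[None, :])
        res = t_test_two_group(m, DESIGN_33, "A", "B")
        assert np.isnan(res.table["statistic"].iloc[0])

    def test_unknown_group_rejected(self):
        m = make_log2_matrix(np.ones((2, 6)))
        with pytest.raises(ProtNormError):
            t_test_two_group(m, DESIGN_33, "A", "C")

    def test_null_p_values_are_uniform(self):
        # Kolmogorov–Smirnov check of the Welch p-value distribution at
        # n = 5000 proteins, 3 vs 3, no effect
        rng = np.random.default_rng(42)
        m = make_log2_matrix(rng.normal(20, 1, size=(5000, 6)))
        res = t_test_two_group(m, DESIGN_33, "A", "B")
        p = res.table["p_or_fdr"].dropna().to_numpy()
        d = stats.kstest(p, "uniform").statistic
        assert d < 0.05


class TestRoc:
    def test_perfect_separation(self):
        res = roc_auc(np.array([3.0, 4.0, 1.0, 2.0]),
                      np.array([True, True, False, False]))
        assert res.auc == 1.0
        assert (res.n_pos, res.n_neg) == (2, 2)

    def test_all_tied_scores_give_half(self):
        res = roc_auc(np.ones(10), np.array([True] * 3 + [False] * 7))
        assert res.auc == pytest.approx(0.5)

    def test_interleaved_example(self):
        # spikes {2,4} vs background {1,3}: 3 wins of 4 pairs
        res = roc_auc(np.array([2.0, 4.0, 1.0, 3.0]),
                      np.array([True, True, False, False]))
        assert res.auc == pytest.approx(0.75)

    def test_matches_exhaustive_pair_count_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(5, 80)
            scores = np.round(rng.normal(0, 1, n), 1)  # forces ties
            truth = rng.random(n) < 0.3
            if truth.all() or not truth.any():
                continue
            res = roc_auc(scores, truth)
            pos, neg = scores[truth], scores[~truth]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert res.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_missing_scores_excluded_and_counted(self):
        res = roc_auc(np.array([3.0, np.nan, 1.0, 2.0]),
                      np.array([True, True, False, False]))
        assert res.n_missing_excluded == 1
        assert res.n_pos == 1

    def test_single_class_rejected(self):
        with pytest.raises(ProtNormError):
            roc_auc(np.array([1.0, 2.0]), np.array([True, True]))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_negation_antisymmetry_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.arange(20.0))
        truth = np.zeros(20, bool)
        truth[rng.choice(20, 6, replace=False)] = True
        a1 = roc_auc(scores, truth).auc
        a2 = roc_auc(-scores, truth).auc
        assert a1 + a2 == pytest.approx(1.0)


class TestDeLong:
    def test_identical_scores_give_zero_z(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 40)
        truth = np.arange(40) < 15
        z, p = delong_test(s, s.copy(), truth)
        assert z == 0.0 and p == 1.0

    def test_variance_matches_bootstrap_oracle(self):
        # 2000-replicate bootstrap of the AUC difference as an
        # independent variance estimate; DeLong must agree within 15 %
        rng = np.random.default_rng(2)
        n = 30
        truth = np.arange(n) < 12
        a = rng.normal(0, 1, n) + truth * 1.0
        b = 0.6 * a + rng.normal(0, 0.8, n)
        auc_a, _, _ = _placements_for_test(a, truth)
        z, p = delong_test(a, b, truth)
        diff = roc_auc(a, truth).auc - roc_auc(b, truth).auc
        var_delong = (diff / z) ** 2
        boots = []
        for _ in range(2000):
            idx = np.concatenate([
                rng.choice(np.flatnonzero(truth), truth.sum(), replace=True),
                rng.choice(np.flatnonzero(~truth), (~truth).sum(), replace=True),
            ])
            boots.append(roc_auc(a[idx], truth[idx]).auc
                         - roc_auc(b[idx], truth[idx]).auc)
        var_boot = np.var(boots, ddof=1)
        assert abs(var_delong - var_boot) < 0.15 * var_boot

    def test_single_positive_rejected(self):
        truth = np.zeros(10, bool)
        truth[0] = True
        with pytest.raises(ProtNormError):
            delong_test(np.arange(10.0), np.arange(10.0)[::-1], truth)


def _placements_for_test(scores, truth):
    from protnorm.diffexpr import _placements
    return _placements(scores, truth)


class TestRots:
    def test_bootstrap_count_floor_enforced(self):
        m = make_log2_matrix(np.random.default_rng(0).normal(0, 1, (30, 6)))
        with pytest.raises(ProtNormError):
            rots_test(m, DESIGN_33, "A", "B", B=10)

    def test_statistic_family_matches_welch_ordering_at_alpha_01(self):
        # with (α₁, α₂) = (0, 1), d = |Δmean| / s is |Welch t|
        rng = np.random.default_rng(3)
        x1 = rng.normal(0, 1, (200, 3))
        x2 = rng.normal(0, 1, (200, 3)) + 0.5
        d = _rots_stat(x1, x2, np.array([[0.0, 1.0]]))[0]
        m1, v1 = x1.mean(1), x1.var(1, ddof=1)
        m2, v2 = x2.mean(1), x2.var(1, ddof=1)
        t = np.abs(m2 - m1) / np.sqrt(v1 / 3 + v2 / 3)
        np.testing.assert_allclose(d, t)

    def test_t_family_selected_when_variance_scaling_is_informative(self):
        # per-protein variances spread over ~6x and effects proportional
        # to them: scaling by s separates signal from noise, so the
        # optimizer must choose an α₂ = 1 (t-like) statistic, not the
        # plain fold change, in most seeded runs
        hits = 0
        runs = 5
        design = StudyDesign(groups={f"s{j}": ("A" if j < 5 else "B")
                                     for j in range(10)})
        for i in range(runs):
            rng = np.random.default_rng(200 + i)
            n = 400
            sd = rng.uniform(0.5, 3.0, n)
            V = 20 + rng.normal(0, 1, (n, 10)) * sd[:, None]
            V[:100, 5:] += 2.5 * sd[:100, None]
            m = make_log2_matrix(V)
            res = rots_test(m, design, "A", "B", B=60, seed=i)
            if res.extras["alpha2"] == 1.0:
                hits += 1
        assert hits >= int(0.8 * runs)

    def test_equal_variance_effects_prefer_regularized_denominator(self):
        # with variances equal by construction the pooled SE carries no
        # ranking information, only estimation noise: the optimizer should
        # not select the pure (0, 1) t statistic
        rng = np.random.default_rng(100)
        V = rng.normal(20, 1, size=(300, 8))
        V[:60, 4:] += 2.0
        m = make_log2_matrix(V)
        design = StudyDesign(groups={f"s{j}": ("A" if j < 4 else "B")
                                     for j in range(8)})
        res = rots_test(m, design, "A", "B", B=60, seed=0)
        assert not (res.extras["alpha1"] == 0.0 and res.extras["alpha2"] == 1.0)

    def test_no_signal_falls_back_without_error(self):
        rng = np.random.default_rng(5)
        m = make_log2_matrix(rng.normal(20, 1, size=(200, 6)))
        res = rots_test(m, DESIGN_33, "A", "B", B=50, seed=0)
        assert res.extras["z_score"] < 2.0
        assert np.isfinite(res.table["statistic"].dropna()).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        V = rng.normal(20, 1, size=(120, 6))
        m = make_log2_matrix(V)
        r1 = rots_test(m, DESIGN_33, "A", "B", B=50, seed=9)
        r2 = rots_test(m, DESIGN_33, "A", "B", B=50, seed=9)
        np.testing.assert_array_equal(r1.table["statistic"], r2.table["statistic"])
        assert r1.extras == r2.extras
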