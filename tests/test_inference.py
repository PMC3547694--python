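"""Blocked ANOVA, studentized-range quantiles, Tukey HSD, line grouping."""

import math

import numpy as np
import pytest
from scipy import stats

from incidentqc.inference import (
    line_grouping,
    rcb_anova,
    studentized_range_quantile,
    tukey_hsd,
)

HAND_MATRIX = np.array([[1.0, 3.0], [2.0, 5.0], [3.0, 4.0]])  # 3 blocks x 2 treatments


def brute_force_anova(y):
    """Oracle: explicit mean-based sums over all cells, plain Python loops."""
    b, a = len(y), len(y[0])
    grand = sum(y[i][j] for i in range(b) for j in range(a)) / (a * b)
    col = [sum(y[i][j] for i in range(b)) / b for j in range(a)]
    row = [sum(y[i][j] for j in range(a)) / a for i in range(b)]
    ss_t = sum(b * (cj - grand) ** 2 for cj in col)
    ss_b = sum(a * (ri - grand) ** 2 for ri in row)
    ss_e = sum(
        (y[i][j] - col[j] - row[i] + grand) ** 2
        for i in range(b)
        for j in range(a)
    )
    ss_tot = sum((y[i][j] - grand) ** 2 for i in range(b) for j in range(a))
    return ss_t, ss_b, ss_e, ss_tot


class TestRcbAnova:
    def test_hand_computed_decomposition(self):
        t = rcb_anova(HAND_MATRIX)
        assert t.ss_treatment == pytest.approx(6.0)
        assert t.ss_block == pytest.approx(3.0)
        assert t.ss_error == pytest.approx(1.0)
        assert t.f_treatment == pytest.approx(12.0)
        assert (t.df_treatment, t.df_block, t.df_error, t.df_total) == (1, 2, 2, 5)
        assert t.ss_total == pytest.approx(t.ss_treatment + t.ss_block + t.ss_error)

    def test_identical_columns_give_zero_treatment_effect(self):
        y = np.tile(np.array([[1.0], [4.0], [2.0]]), (1, 3))
        with pytest.warns(UserWarning):  # identical columns are also additive
            t = rcb_anova(y)
        assert t.ss_treatment == pytest.approx(0.0, abs=1e-12)
        assert t.f_treatment == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_additive_matrix_has_zero_error(self):
        tau = np.array([0.0, 1.0, 3.0])
        beta = np.array([0.0, 2.0, 5.0, 7.0])
        y = beta[:, None] + tau[None, :]
        with pytest.warns(UserWarning, match="zero error variance"):
            t = rcb_anova(y)
        assert t.ss_error == pytest.approx(0.0, abs=1e-9)
        assert t.p_treatment == 0.0

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            rcb_anova(np.ones((1, 5)))
        with pytest.raises(ValueError):
            rcb_anova(np.ones((5, 1)))

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = int(rng.integers(2, 9))
        b = int(rng.integers(3, 13))
        y = rng.normal(size=(b, a)) * 3 + rng.normal()
        t = rcb_anova(y)
        ss_t, ss_b, ss_e, ss_tot = brute_force_anova(y.tolist())
        assert t.ss_treatment == pytest.approx(ss_t, rel=1e-9)
        assert t.ss_block == pytest.approx(ss_b, rel=1e-9)
        assert t.ss_error == pytest.approx(ss_e, rel=1e-9, abs=1e-9)
        assert t.ss_total == pytest.approx(ss_tot, rel=1e-9)

    def test_agrees_with_statsmodels_ols(self):
        """Independent route: two-way additive OLS fit with anova_lm."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(42)
        b, a = 7, 4
        y = rng.integers(0, 3, size=(b, a)).astype(float)
        frame = pd.DataFrame(
            {
                "y": y.ravel(),
                "block": np.repeat(np.arange(b), a).astype(str),
                "treat": np.tile(np.arange(a), b).astype(str),
            }
        )
        fit = ols("y ~ C(block) + C(treat)", data=frame).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        mine = rcb_anova(y)
        assert mine.ss_treatment == pytest.approx(table.loc["C(treat)", "sum_sq"])
        assert mine.ss_block == pytest.approx(table.loc["C(block)", "sum_sq"])
        assert mine.ss_error == pytest.approx(table.loc["Residual", "sum_sq"])
        assert mine.f_treatment == pytest.approx(table.loc["C(treat)", "F"])
        assert mine.p_treatment == pytest.approx(table.loc["C(treat)", "PR(>F)"])

    def test_block_permutation_changes_nothing(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(6, 4))
        t1 = rcb_anova(y)
        t2 = rcb_anova(y[rng.permutation(6)])
        assert t1.ss_treatment == pytest.approx(t2.ss_treatment)
        assert t1.ss_block == pytest.approx(t2.ss_block)
        assert t1.f_treatment == pytest.approx(t2.f_treatment)


class TestStudentizedRange:
    def test_two_means_reduce_to_scaled_t(self):
        # q = sqrt(2) * t for k = 2
        t975 = stats.t.ppf(0.975, 2)
        assert studentized_range_quantile(0.95, 2, 2) == pytest.approx(
            math.sqrt(2) * t975, rel=1e-4
        )
        assert studentized_range_quantile(0.95, 2, 2) == pytest.approx(6.085, abs=2e-3)

    def test_large_df_limit_is_scaled_normal(self):
        z975 = stats.norm.ppf(0.975)
        assert studentized_range_quantile(0.95, 2, 1e6) == pytest.approx(
            math.sqrt(2) * z975, rel=1e-3
        )

    def test_monotone_in_number_of_means(self):
        qs = [studentized_range_quantile(0.95, k, 30) for k in (2, 3, 5, 8, 11)]
        assert all(q1 < q2 for q1, q2 in zip(qs, qs[1:]))

    def test_invalid_arguments_rejected(self):
        for bad in [(0.0, 3, 10), (0.95, 1, 10), (0.95, 3, 0.5)]:
            with pytest.raises(ValueError):
                studentized_range_quantile(*bad)


class TestTukey:
    def test_hand_example_threshold_and_flags(self):
        res = tukey_hsd(HAND_MATRIX, alpha=0.05)
        expected_hsd = studentized_range_quantile(0.95, 2, 2) * math.sqrt(0.5 / 3)
        assert res.hsd == pytest.approx(expected_hsd, rel=1e-6)
        assert res.hsd == pytest.approx(2.484, abs=2e-3)
        (pair,) = res.pairs.to_dict("records")
        assert pair["mean_diff"] == pytest.approx(2.0)
        assert not pair["significant"]  # |2| < 2.484

    def test_identical_treatments_never_differ(self):
        col = np.array([0.0, 1.0, 2.0, 1.0])
        with pytest.warns(UserWarning):  # duplicated column => zero error variance
            res = tukey_hsd(np.column_stack([col, col]))
        (pair,) = res.pairs.to_dict("records")
        assert pair["mean_diff"] == 0.0
        assert not pair["significant"]

    def test_significance_consistent_with_adjusted_p(self, calibration_matrix):
        res = tukey_hsd(calibration_matrix, alpha=0.05)
        flagged = res.pairs["significant"]
        assert (res.pairs.loc[flagged, "p_adj"] < 0.05).all()
        assert (res.pairs.loc[~flagged, "p_adj"] >= 0.05).all()
        # flag definition: |diff| > hsd
        assert (
            flagged == (res.pairs["mean_diff"].abs() > res.hsd)
        ).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_two_treatments_match_paired_t_test(self, seed):
        """For a = 2, Tukey's adjusted p equals the paired two-sided t-test."""
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(9, 2)) + rng.normal(scale=0.5, size=(9, 1))
        res = tukey_hsd(y, alpha=0.05)
        (pair,) = res.pairs.to_dict("records")
        t_p = stats.ttest_rel(y[:, 0], y[:, 1]).pvalue
        assert pair["p_adj"] == pytest.approx(t_p, rel=1e-6)
        assert pair["significant"] == (t_p < 0.05)

    def test_zero_error_variance_flags_every_difference(self):
        tau = np.array([0.0, 1.0])
        beta = np.arange(4, dtype=float)
        y = beta[:, None] + tau[None, :]
        with pytest.warns(UserWarning):
            res = tukey_hsd(y)
        (pair,) = res.pairs.to_dict("records")
        assert pair["significant"] and pair["p_adj"] == 0.0

    def test_treatment_label_permutation_permutes_output(self, calibration_matrix):
        y = np.asarray(calibration_matrix.cells, dtype=float)
        perm = np.random.default_rng(3).permutation(y.shape[1])
        res1 = tukey_hsd(y)
        res2 = tukey_hsd(y[:, perm])
        assert res1.hsd == pytest.approx(res2.hsd)
        assert sorted(np.round(res1.pairs.p_adj, 12)) == sorted(
            np.round(res2.pairs.p_adj, 12)
        )


class TestLineGrouping:
    def test_two_groups(self):
        assert line_grouping([1.0, 1.1, 2.0], 0.5) == [(0, 1), (2,)]

    def test_overlapping_groups(self):
        assert line_grouping([1.0, 1.4, 1.8], 0.5) == [(0, 1), (1, 2)]

    def test_huge_hsd_single_group(self):
        assert line_grouping([3.0, 1.0, 2.0], 10.0) == [(1, 2, 0)]

    def test_labels_reported_in_original_terms(self):
        groups = line_grouping([0.5, 0.1], 0.1, labels=["a", "b"])
        assert groups == [("b",), ("a",)]

    @pytest.mark.parametrize("seed", range(5))
    def test_soundness_on_random_means(self, seed):
        """Groups cover everything; sharing a group <=> |diff| <= hsd."""
        rng = np.random.default_rng(seed)
        means = rng.uniform(0, 2, size=11)
        hsd = float(rng.uniform(0.05, 1.0))
        groups = line_grouping(means, hsd)
        covered = set().union(*map(set, groups))
        assert covered == set(range(11))
        share = {
            (i, j): any(i in g and j in g for g in map(set, groups))
            for i in range(11)
            for j in range(i + 1, 11)
        }
        for (i, j), shared in share.items():
            assert shared == (abs(means[i] - means[j]) <= hsd)
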