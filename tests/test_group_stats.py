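"""Rank-sum inference, OLS fit, cohort report."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boldcv.group_stats import (
    CohortTable,
    compare_cohorts,
    linear_fit,
    wilcoxon_ranksum,
)


def brute_force_ranksum_p(x, y):
    """Oracle: enumerate every label assignment of the pooled sample."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    s_obs = ranks[:n1].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n1)])
    p_le = np.mean(sums <= s_obs + 1e-9)
    p_ge = np.mean(sums >= s_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonExact:
    def test_minimal_example(self):
        # x={1,2}, y={3,4}: 6 assignments, the observed rank-sum is extreme
        res = wilcoxon_ranksum([1, 2], [3, 4])
        assert res.p_two_sided == pytest.approx(2 / 6)
        assert res.method == "exact"
        assert res.statistic == 3.0

    def test_identical_multisets_p_one(self):
        res = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_sided == 1.0

    def test_degenerate_all_equal_warns(self):
        with pytest.warns(UserWarning, match="degenerate|identical"):
            res = wilcoxon_ranksum([5.0, 5.0], [5.0, 5.0])
        assert res.p_two_sided == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 5), (3, 4), (4, 4), (5, 6), (6, 6)])
    def test_exact_equals_brute_force_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + rng.uniform(-1, 1)
            res = wilcoxon_ranksum(x, y)
            assert res.method == "exact"
            assert res.p_two_sided == pytest.approx(brute_force_ranksum_p(x, y))

    def test_tied_data_equals_brute_force(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0]
        res = wilcoxon_ranksum(x, y)
        assert res.method == "exact_perm"
        assert res.p_two_sided == pytest.approx(brute_force_ranksum_p(x, y))

    def test_exact_close_to_normal_approx_at_n10(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10) + 0.5
            exact = wilcoxon_ranksum(x, y).p_two_sided
            approx = wilcoxon_ranksum(x, y, exact_limit=0).p_two_sided
            assert abs(exact - approx) < 0.01

    def test_agrees_with_scipy_exact(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        x = rng.standard_normal(8)
        y = rng.standard_normal(9) + 0.8
        ours = wilcoxon_ranksum(x, y).p_two_sided
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(6)
        y = rng.standard_normal(7) + 0.3
        base = wilcoxon_ranksum(x, y).p_two_sided
        for f in (np.exp, lambda v: 3 * v - 7, lambda v: v**3):
            assert wilcoxon_ranksum(f(x), f(y)).p_two_sided == pytest.approx(base)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            wilcoxon_ranksum([1.0], [2.0, 3.0])

    def test_cohorts_at_reported_levels_significant(self):
        """Group-level CV distributions this different give p well below 0.01."""
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(21):
            control = rng.normal(4.6e-3, 0.6e-3, 10)
            ckd = rng.normal(7.9e-3, 1.8e-3, 10)
            ps.append(wilcoxon_ranksum(control, ckd).p_two_sided)
        assert np.median(ps) < 0.01


class TestLinearFit:
    def test_collinear_points(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_fit(x, 0.36 * x + 0.0014)
        assert fit.slope == pytest.approx(0.36)
        assert fit.intercept == pytest.approx(0.0014)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        fit = linear_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_five_point_fixture_matches_normal_equations(self, rng):
        x = rng.standard_normal(5)
        y = 2 * x + rng.standard_normal(5)
        X = np.column_stack([x, np.ones(5)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        fit = linear_fit(x, y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        resid = y - slope * x - intercept
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert fit.r_squared == pytest.approx(r2)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _table(rows):
    return CohortTable(data=pd.DataFrame(rows, columns=["subject", "group", "tissue",
                                                        "method", "band", "cv", "n"]))


class TestCompareCohorts:
    def _rows(self, values_by_group):
        rows = []
        for group, values in values_by_group.items():
            for i, v in enumerate(values):
                sid = f"{group}{i}"
                rows.append([sid, group, "GM", "strict", "full", v, 1000])
        return rows

    def test_identical_groups_p_one_zero_difference(self):
        vals = [3.0, 4.0, 5.0]
        table = _table(self._rows({"control": vals, "ckd": vals}))
        report = compare_cohorts(table)
        row = report.strata.iloc[0]
        assert row["p"] == 1.0
        assert row["mean_control"] == pytest.approx(row["mean_ckd"])

    def test_hand_built_four_subject_table(self):
        table = _table(self._rows({"control": [1.0, 2.0], "ckd": [3.0, 4.0]}))
        report = compare_cohorts(table)
        row = report.strata.iloc[0]
        assert row["mean_control"] == pytest.approx(1.5)
        assert row["sd_control"] == pytest.approx(np.std([1.0, 2.0], ddof=1))
        assert row["mean_ckd"] == pytest.approx(3.5)
        assert row["p"] == pytest.approx(2 / 6)

    def test_incomplete_strata_listed_and_skipped(self):
        rows = self._rows({"control": [1.0, 2.0], "ckd": [3.0, 4.0]})
        rows.append(["ckd0", "ckd", "WM", "strict", "full", 2.0, 500])
        report = compare_cohorts(_table(rows))
        assert report.incomplete == ["WM/strict/full"]
        assert len(report.strata) == 1

    def test_subject_in_two_groups_rejected(self):
        rows = [["s1", "control", "GM", "strict", "full", 1.0, 10],
                ["s1", "ckd", "GM", "strict", "full", 2.0, 10]]
        with pytest.raises(ValueError, match="more than one group"):
            _table(rows)

    def test_gm_wm_fit_present_with_both_tissues(self):
        rows = []
        rng = np.random.default_rng(5)
        for group, base in (("control", 4.6e-3), ("ckd", 7.9e-3)):
            for i in range(5):
                gm = base + 1e-4 * rng.standard_normal()
                wm = 0.36 * gm + 0.0014
                sid = f"{group}{i}"
                rows.append([sid, group, "GM", "strict", "full", gm, 1000])
                rows.append([sid, group, "WM", "strict", "full", wm, 800])
        report = compare_cohorts(_table(rows))
        assert report.gm_wm_fit is not None
        assert report.gm_wm_fit.slope == pytest.approx(0.36, rel=1e-6)
        assert report.gm_wm_fit.r_squared == pytest.approx(1.0)
        assert "WM vs GM fit" in report.summary()
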