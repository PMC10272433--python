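import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bgfc.stats import (
    DegenerateVarianceError,
    TwoGroupSummary,
    bh_fdr,
    correlation_table,
    mixed_anova_2x2,
    paired_t,
    two_sample_t,
    two_sample_t_from_data,
)


class TestTwoSampleT:
    def test_df_for_retained_cohort_sizes(self):
        res = two_sample_t(TwoGroupSummary(36, 37, 1.0, 0.9, 0.2, 0.2))
        assert res.df == 71

    def test_cohens_d_from_printed_group_summaries(self):
        # extrinsic putamen-pallidum group summaries: means 1.18 vs 1.05,
        # SDs 0.21 vs 0.23, n 36 vs 37
        res = two_sample_t(TwoGroupSummary(36, 37, 1.18, 1.05, 0.21, 0.23))
        assert round(res.d, 2) == 0.59
        assert res.df == 71

    def test_equal_means_give_zero(self):
        res = two_sample_t(TwoGroupSummary(10, 12, 5.0, 5.0, 1.0, 1.2))
        assert res.t == pytest.approx(0.0)
        assert res.d == pytest.approx(0.0)

    def test_zero_variance_overflow(self):
        with pytest.raises(DegenerateVarianceError):
            two_sample_t(TwoGroupSummary(5, 5, 1.0, 2.0, 0.0, 0.0))

    def test_matches_scipy_on_data(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(25) + 0.3
        res = two_sample_t_from_data(x, y)
        ref = sps.ttest_ind(x, y)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_df_is_fractional(self, rng):
        x = rng.standard_normal(15) * 3
        y = rng.standard_normal(40) * 0.5
        res = two_sample_t_from_data(x, y, welch=True)
        assert res.welch
        assert res.df != round(res.df) or res.df < 53

    def test_type_I_error_calibrated_at_five_percent(self):
        rng = np.random.default_rng(314)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.standard_normal(36)
            y = rng.standard_normal(37)
            if two_sample_t_from_data(x, y).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestPairedT:
    def test_identical_series_give_zero(self):
        x = np.arange(5.0)
        res = paired_t(x, x)
        assert res.t == 0.0 and res.df == 4

    def test_constant_nonzero_difference_overflows(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateVarianceError):
            paired_t(x, x + 1.0)

    def test_matches_one_sample_on_differences(self, rng):
        x = rng.standard_normal(19)
        y = x + 0.2 + 0.5 * rng.standard_normal(19)
        res = paired_t(x, y)
        ref = sps.ttest_1samp(x - y, 0.0)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 18


def _anova_oracle(table):
    """Explicit sums-of-squares decomposition of the 2x2 mixed design."""
    piv = table.pivot_table(index=["group", "subject"], columns="task", values="rt")
    groups = piv.index.get_level_values("group")
    X = piv.to_numpy()
    GM = X.mean()
    subj_means = X.mean(axis=1)
    level_means = X.mean(axis=0)
    N = X.shape[0]
    ss = {}
    g_labels = sorted(set(groups))
    n_g = {g: (groups == g).sum() for g in g_labels}
    g_means = {g: X[groups == g].mean() for g in g_labels}
    cell_means = {g: X[groups == g].mean(axis=0) for g in g_labels}
    ss["A"] = 2 * sum(n_g[g] * (g_means[g] - GM) ** 2 for g in g_labels)
    ss["S_A"] = 2 * sum(
        ((subj_means[groups == g] - g_means[g]) ** 2).sum() for g in g_labels
    )
    ss["B"] = N * ((level_means - GM) ** 2).sum()
    ss["AB"] = sum(
        n_g[g] * ((cell_means[g] - g_means[g] - level_means + GM) ** 2).sum()
        for g in g_labels
    )
    ss["B_S_A"] = sum(
        (
            (X[groups == g] - subj_means[groups == g][:, None]
             - cell_means[g][None, :] + g_means[g]) ** 2
        ).sum()
        for g in g_labels
    )
    df_s = N - 2
    out = {
        "diagnosis": (ss["A"] / (ss["S_A"] / df_s), 1, df_s, ss["A"] / (ss["A"] + ss["S_A"])),
        "task": (ss["B"] / (ss["B_S_A"] / df_s), 1, df_s, ss["B"] / (ss["B"] + ss["B_S_A"])),
        "interaction": (ss["AB"] / (ss["B_S_A"] / df_s), 1, df_s, ss["AB"] / (ss["AB"] + ss["B_S_A"])),
    }
    ss_total = ((X - GM) ** 2).sum()
    assert abs(sum(ss.values()) - ss_total) <= 1e-8 * max(ss_total, 1.0)
    return out


def _rt_table(rng, n_per_group=6, effect=0.0):
    rows = []
    for gi, g in enumerate(("HC", "MS")):
        for i in range(n_per_group):
            base = 400 + 40 * rng.standard_normal() + gi * effect
            for t, shift in (("T2", 0.0), ("T3", -15.0)):
                rows.append((f"{g}{i}", g, t, base + shift + 10 * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["subject", "group", "task", "rt"])


class TestMixedAnova:
    def test_hand_built_table_matches_ss_oracle(self):
        rows = []
        data = {
            ("HC", "s1"): (410.0, 380.0),
            ("HC", "s2"): (430.0, 400.0),
            ("MS", "s3"): (480.0, 455.0),
            ("MS", "s4"): (520.0, 470.0),
        }
        for (g, s), (t2, t3) in data.items():
            rows += [(s, g, "T2", t2), (s, g, "T3", t3)]
        table = pd.DataFrame(rows, columns=["subject", "group", "task", "rt"])
        res = mixed_anova_2x2(table)
        oracle = _anova_oracle(table)
        got = res.as_dict()
        for effect in ("diagnosis", "task", "interaction"):
            F, df1, df2, eta = oracle[effect]
            assert got[effect]["F"] == pytest.approx(F, abs=1e-10)
            assert got[effect]["df1"] == df1
            assert got[effect]["df2"] == df2
            assert got[effect]["partial_eta_sq"] == pytest.approx(eta, abs=1e-10)

    def test_random_table_matches_oracle(self, rng):
        table = _rt_table(rng, n_per_group=9, effect=60.0)
        res = mixed_anova_2x2(table).as_dict()
        oracle = _anova_oracle(table)
        for effect in ("diagnosis", "task", "interaction"):
            assert res[effect]["F"] == pytest.approx(oracle[effect][0], rel=1e-9)

    def test_df_with_73_subjects_is_1_71(self, rng):
        rows = []
        for g, n in (("HC", 36), ("MS", 37)):
            for i in range(n):
                for t in ("T2", "T3"):
                    rows.append((f"{g}{i}", g, t, 400 + 30 * rng.standard_normal()))
        res = mixed_anova_2x2(pd.DataFrame(rows, columns=["subject", "group", "task", "rt"]))
        assert res.diagnosis[1:3] == (1.0, 71.0)

    def test_null_data_small_effects(self, rng):
        table = _rt_table(rng, n_per_group=20, effect=0.0)
        res = mixed_anova_2x2(table).as_dict()
        assert res["interaction"]["partial_eta_sq"] < 0.2

    def test_missing_cell_errors(self, rng):
        table = _rt_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="missing within-level"):
            mixed_anova_2x2(table)


class TestCorrelations:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(30)})
        df["y"] = df["x"]
        (cell,) = correlation_table(df, [("x", "y")])
        assert cell.r == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        df = pd.DataFrame(rng.standard_normal((40, 2)), columns=["x", "y"])
        (cell,) = correlation_table(df, [("x", "y")])
        x, y = df["x"] - df["x"].mean(), df["y"] - df["y"].mean()
        assert cell.r == pytest.approx((x @ y) / np.sqrt((x @ x) * (y @ y)), abs=1e-12)

    def test_null_simulation_centred_on_zero(self):
        rng = np.random.default_rng(99)
        rs = []
        for _ in range(500):
            x = rng.standard_normal(73)
            y = rng.standard_normal(73)
            rs.append(sps.pearsonr(x, y)[0])
        se = 1 / np.sqrt(70) / np.sqrt(500)
        assert abs(np.mean(rs)) <= 3 * se

    def test_grouped_cells(self, rng):
        df = pd.DataFrame({
            "g": ["a"] * 10 + ["b"] * 10,
            "x": rng.standard_normal(20),
            "y": rng.standard_normal(20),
        })
        cells = correlation_table(df, [("x", "y")], group_col="g")
        assert [c.group for c in cells] == ["a", "b"]
        assert all(c.n == 10 for c in cells)


class TestBhFdr:
    def test_step_up_rule_by_hand(self):
        flags = bh_fdr([0.01, 0.04, 0.30, 0.50], q=0.10)
        # thresholds k*q/m = .025, .05, .075, .10 -> largest k with
        # p_(k) <= thr is k=2 -> reject the two smallest
        np.testing.assert_array_equal(flags, [True, True, False, False])

    def test_all_tiny_p_rejected(self):
        assert bh_fdr([0.001] * 10, q=0.10).all()

    def test_empty_list(self):
        assert bh_fdr([]).size == 0

    def test_matches_direct_step_up_oracle(self, rng):
        p = rng.uniform(size=25)
        flags = bh_fdr(p, q=0.10)
        order = np.argsort(p)
        m = len(p)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * 0.10 / m:
                k_max = rank
        expected = np.zeros(m, bool)
        expected[order[:k_max]] = True
        np.testing.assert_array_equal(flags, expected)

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=30)
        prev = None
        for q in (0.20, 0.10, 0.05, 0.01):
            cur = set(np.where(bh_fdr(p, q))[0])
            if prev is not None:
                assert cur <= prev  # lowering q never adds rejections
            prev = cur

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([0.5], q=1.5)
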