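"""The pre/post battery against independent oracles (scipy, pingouin,
enumeration, brute-force sums of squares)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wristmetrics.stats import (
    CohortAnalysis,
    StatConfig,
    _orthonormal_contrasts,
    describe,
    hedges_g_paired,
    manova_pillai_within,
    normality_screen,
    paired_t,
    rm_anova_within,
    wilcoxon_signed_rank,
)
from wristmetrics.io_formats import CohortTable

# per-child affected-arm intensity percentages (dominant band, 8 children,
# early vs late training sessions) used as a realistic worked example
LIGHT_EARLY = [98.86, 78, 83.69, 76.55, 70.56, 60.04, 76.22, 90.39]
LIGHT_LATE = [97.73, 80.18, 91.84, 86.36, 74.39, 75.95, 88.43, 89.49]


class TestDescribe:
    def test_worked_example_mean_se(self):
        d = describe(LIGHT_EARLY)
        assert d["mean"] == pytest.approx(79.29, abs=0.005)
        assert d["se"] == pytest.approx(4.21, abs=0.005)

    def test_constant_vector(self):
        d = describe([5.0, 5.0, 5.0])
        assert d["se"] == 0.0
        assert d["iqr"] == 0.0

    def test_skewness_sign(self):
        assert describe([0.0, 0.0, 12.0])["skewness"] > 0

    def test_quartiles_linear_interpolation(self, rng):
        x = rng.normal(size=11)
        d = describe(x)
        assert d["q1"] == pytest.approx(np.percentile(x, 25))
        assert d["iqr"] == pytest.approx(sps.iqr(x))

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            describe([1.0])


class TestNormalityScreen:
    def test_normal_sample_routed_parametric(self, rng):
        x = rng.normal(size=20)
        res = normality_screen(x)
        assert res["decision"] == "parametric"
        w_ref, p_ref = sps.shapiro(x)
        assert res["shapiro_w"] == pytest.approx(w_ref, abs=1e-6)
        assert res["shapiro_p"] == pytest.approx(p_ref, abs=1e-6)

    def test_point_mass_routed_nonparametric(self):
        res = normality_screen([0.0] * 7 + [100.0])
        assert res["decision"] == "nonparametric"

    def test_scale_invariant(self, rng):
        x = rng.normal(size=15)
        assert normality_screen(x)["decision"] == normality_screen(10 * x)["decision"]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])


class TestPairedT:
    def test_worked_example_statistic(self):
        res = paired_t(LIGHT_EARLY, LIGHT_LATE)
        assert res.statistic == pytest.approx(-2.833, abs=0.001)
        assert res.df == 7
        assert res.p_value == pytest.approx(0.025, abs=0.001)

    def test_no_change_gives_unit_p(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_matches_one_sample_t_on_differences(self, rng):
        pre, post = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(pre, post)
        ref = sps.ttest_1samp(pre - post, 0.0)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_effect_size_is_hedges_g(self):
        res = paired_t(LIGHT_EARLY, LIGHT_LATE)
        d = np.array(LIGHT_EARLY) - np.array(LIGHT_LATE)
        j = 1 - 3 / (4 * 7 - 1)
        assert res.effect_size == pytest.approx(j * d.mean() / d.std(ddof=1))


class TestWilcoxon:
    def test_exact_small_sample_enumeration(self):
        # d = (1,2,3): all positive; one-sided tail mass of max W+ is 1/8,
        # two-sided doubles it
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.p_value == pytest.approx(2 / 8)

    def test_pre_post_swap_leaves_p_unchanged(self, rng):
        pre, post = rng.normal(size=9), rng.normal(size=9)
        assert wilcoxon_signed_rank(pre, post).p_value == pytest.approx(
            wilcoxon_signed_rank(post, pre).p_value
        )

    def test_matches_scipy_exact(self, rng):
        for _ in range(5):
            pre, post = rng.normal(size=10), rng.normal(size=10)
            mine = wilcoxon_signed_rank(pre, post)
            ref = sps.wilcoxon(pre, post, method="exact")
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.p_value == pytest.approx(ref.pvalue)

    def test_matches_brute_force_enumeration_with_ties(self):
        pre = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.0, 6.0])
        post = np.array([2.0, 2.0, 2.0, 1.5 + 1.0, 5.0, 4.0, 6.5])
        d = pre - post
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
        n = len(d)
        total = ranks.sum()
        w_obs = ranks[d > 0].sum()
        w_tail = min(w_obs, total - w_obs)
        hits = 0
        for mask in range(2**n):
            w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
            if w <= w_tail + 1e-9 or w >= total - w_tail - 1e-9:
                hits += 1
        res = wilcoxon_signed_rank(pre, post)
        assert res.p_value == pytest.approx(hits / 2**n)

    def test_exact_vs_normal_approximation_close_at_n12(self, rng):
        pre = rng.normal(size=12)
        post = pre + rng.normal(0.5, 1.0, size=12)
        exact = wilcoxon_signed_rank(pre, post).p_value
        ref = sps.wilcoxon(pre, post, method="approx", correction=True).pvalue
        assert abs(exact - ref) < 0.02

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestRmAnova:
    def _brute_force_ss(self, y):
        """Direct sums-of-squares from cell means (independent oracle)."""
        n, a, b = y.shape
        g = y.mean()
        ss = {}
        ss["a"] = n * b * sum((y[:, i, :].mean() - g) ** 2 for i in range(a))
        ss["b"] = n * a * sum((y[:, :, j].mean() - g) ** 2 for j in range(b))
        ss["ab"] = n * sum(
            (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + g) ** 2
            for i in range(a) for j in range(b)
        )
        ss["as"] = b * sum(
            (y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + g) ** 2
            for s in range(n) for i in range(a)
        )
        return ss

    def test_identical_level_means_give_zero_f(self):
        y = np.tile(np.arange(5, dtype=float)[:, None, None], (1, 3, 2))
        res = rm_anova_within(y)
        assert res["factor_a"].statistic == 0.0
        assert res["factor_b"].statistic == 0.0

    def test_two_level_factor_has_unit_epsilon(self, rng):
        y = rng.normal(size=(6, 4, 2))
        res = rm_anova_within(y)
        assert res["factor_b"].assumptions["gg_epsilon"] == 1.0
        assert res["factor_b"].assumptions["mauchly_p"] == 1.0

    def test_ss_decomposition_matches_brute_force(self, rng):
        y = rng.normal(size=(5, 4, 2)) + rng.normal(size=(5, 1, 1))
        res = rm_anova_within(y)
        ss = self._brute_force_ss(y)
        assert res["factor_a"].assumptions["ss_effect"] == pytest.approx(ss["a"])
        assert res["factor_a"].assumptions["ss_error"] == pytest.approx(ss["as"])
        assert res["factor_a*factor_b"].assumptions["ss_effect"] == pytest.approx(ss["ab"])

    def test_matches_pingouin_two_way(self, rng):
        pg = pytest.importorskip("pingouin")
        n, a, b = 8, 4, 2
        y = rng.normal(size=(n, a, b)) + 0.5 * np.arange(a)[None, :, None]
        res = rm_anova_within(y, ("act", "time"))
        df = pd.DataFrame(
            [
                {"subj": s, "act": i, "time": j, "y": y[s, i, j]}
                for s in range(n) for i in range(a) for j in range(b)
            ]
        )
        ref = pg.rm_anova(
            data=df, dv="y", within=["act", "time"], subject="subj",
            detailed=True, effsize="np2",
        ).set_index("Source")
        for mine, theirs in [("act", "act"), ("time", "time"), ("act*time", "act * time")]:
            assert res[mine].statistic == pytest.approx(ref.loc[theirs, "F"], rel=1e-6)
            assert res[mine].effect_size == pytest.approx(ref.loc[theirs, "np2"], rel=1e-6)
            assert res[mine].assumptions["gg_epsilon"] == pytest.approx(
                ref.loc[theirs, "eps"], rel=1e-6
            )

    def test_gg_correction_applied_when_mauchly_rejects(self, rng):
        # strongly non-spherical: one contrast direction dominates
        n, a = 12, 4
        base = rng.normal(size=(n, 1)) * [5.0, 0.2, 0.2, 0.2] + rng.normal(size=(n, a)) * 0.3
        y = np.stack([base, base + rng.normal(size=(n, a)) * 0.1], axis=2)
        res = rm_anova_within(y)
        info = res["factor_a"].assumptions
        if info["mauchly_p"] < 0.05:
            assert info["gg_applied"]
            df1, df2 = res["factor_a"].df
            assert df1 < a - 1

    def test_missing_cells_rejected(self):
        y = np.ones((4, 3, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_within(y)


class TestManovaPillai:
    def test_no_change_gives_zero(self, rng):
        pre = rng.normal(size=(8, 4))
        res = manova_pillai_within(pre, pre.copy())
        assert res["time"].statistic == 0.0
        assert res["subdomain*time"].statistic == 0.0
        assert res["subdomain*time"].effect_size == 0.0

    def test_single_response_reduces_to_squared_paired_t(self, rng):
        pre, post = rng.normal(size=9), rng.normal(size=9)
        res = manova_pillai_within(pre, post)
        t = paired_t(pre, post)
        assert res["time"].statistic == pytest.approx(t.statistic**2)
        assert res["time"].p_value == pytest.approx(t.p_value)

    def test_df_pattern_for_eleven_subjects_four_subdomains(self, rng):
        pre = rng.normal(size=(11, 4))
        post = pre + rng.normal(0.5, 1, size=(11, 4))
        res = manova_pillai_within(pre, post)
        assert res["time"].df == (1.0, 10.0)
        assert res["subdomain*time"].df == (3.0, 8.0)

    def test_interaction_matches_hotelling_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        pre = rng.normal(size=(10, 4))
        post = pre + rng.normal(0.3, 1, size=(10, 4))
        res = manova_pillai_within(pre, post)
        z = (post - pre) @ _orthonormal_contrasts(4)
        ref = pg.multivariate_ttest(z)
        assert res["subdomain*time"].statistic == pytest.approx(ref.loc["hotelling", "F"])
        assert res["subdomain*time"].p_value == pytest.approx(ref.loc["hotelling", "pval"])

    def test_too_few_subjects_rejected(self, rng):
        x = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="subjects"):
            manova_pillai_within(x, x)


class TestHedgesG:
    def test_correction_factor_at_n8(self):
        # J = 1 − 3/(4·7 − 1) = 8/9
        d = np.array(LIGHT_LATE) - np.array(LIGHT_EARLY)
        g, _, _ = hedges_g_paired(LIGHT_EARLY, LIGHT_LATE)
        dz = d.mean() / d.std(ddof=1)
        assert g == pytest.approx((1 - 3 / 27) * dz)
        assert 1 - 3 / 27 == pytest.approx(0.888888, abs=1e-5)

    def test_correction_vanishes_for_large_n(self, rng):
        pre = rng.normal(size=5000)
        post = pre + rng.normal(0.5, 1, size=5000)
        g, _, _ = hedges_g_paired(pre, post)
        d = post - pre
        assert g == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-3)

    def test_ci_endpoints_satisfy_noncentral_tail_property(self, rng):
        # independent Monte-Carlo oracle: at the lower CI endpoint's
        # noncentrality the observed t should sit at the 97.5th percentile
        # of the paired-t sampling distribution (and at 2.5 for the upper)
        n = 20
        pre = rng.normal(size=n)
        post = pre + rng.normal(0.6, 0.8, size=n)
        g, lo, hi = hedges_g_paired(pre, post)
        assert lo < g < hi
        d = post - pre
        t_obs = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        j = 1 - 3 / (4 * (n - 1) - 1)
        for endpoint, target in ((lo, 0.975), (hi, 0.025)):
            mu = endpoint / j  # d_z at the endpoint
            sims = rng.normal(mu, 1.0, size=(20000, n))
            t_sim = sims.mean(axis=1) / (sims.std(ddof=1, axis=1) / math.sqrt(n))
            assert np.mean(t_sim <= t_obs) == pytest.approx(target, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            hedges_g_paired([1.0, 2.0], [2.0, 3.0])


class TestCohortAnalysis:
    def _cohort(self, rng, shift=6.0, n=8):
        rows = []
        for i in range(n):
            early_mod = rng.normal(75, 5)
            late_mod = early_mod + shift + rng.normal(0, 2)
            for phase, mod in (("early", early_mod), ("late", late_mod)):
                sed = rng.uniform(1, 4)
                vig = rng.uniform(0, 2)
                light = 100 - mod - sed - vig
                rows.append({
                    "child_id": f"c{i:02d}", "phase": phase,
                    "pct_sedentary": sed, "pct_light": light,
                    "pct_moderate": mod, "pct_vigorous": vig,
                    "use_ratio": rng.normal(1.0, 0.05),
                })
        return CohortTable(pd.DataFrame(rows))

    def test_configured_shift_flagged_significant(self, rng):
        res = CohortAnalysis(self._cohort(rng, shift=6.0)).fit()
        row = [r for r in res.summary_rows() if r["outcome"] == "pct_moderate"][0]
        assert row["flag"] == "*"
        assert res.tests["planned[pct_moderate]"].p_value < 0.05

    def test_report_cell_format(self, rng):
        res = CohortAnalysis(self._cohort(rng)).fit()
        row = [r for r in res.summary_rows() if r["outcome"] == "pct_moderate"][0]
        assert len(row["early"].split(" ")) == 2  # "mean (se)"

    def test_deterministic_given_table(self, rng):
        table = self._cohort(rng)
        f1 = CohortAnalysis(table).fit().tests_frame()
        f2 = CohortAnalysis(table).fit().tests_frame()
        pd.testing.assert_frame_equal(f1, f2)

    def test_fewer_than_two_children_rejected(self):
        df = pd.DataFrame({
            "child_id": ["a", "a"], "phase": ["early", "late"], "use_ratio": [1.0, 1.1]
        })
        with pytest.raises(ValueError, match="2 children"):
            CohortAnalysis(CohortTable(df))

    def test_nonparametric_routing_reports_parametric_alongside(self, rng):
        rows = []
        vals_early = [0, 0, 0, 0, 0, 0, 0, 40.0]  # extreme point mass
        for i, v in enumerate(vals_early):
            rows.append({"child_id": f"c{i}", "phase": "early", "pct_sedentary": v})
            rows.append({"child_id": f"c{i}", "phase": "late",
                         "pct_sedentary": max(0.0, v - 1) + 0.1 * i})
        res = CohortAnalysis(CohortTable(pd.DataFrame(rows))).fit()
        test = res.tests["planned[pct_sedentary]"]
        assert test.test_name == "wilcoxon_signed_rank"
        assert "parametric_alongside" in test.assumptions
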