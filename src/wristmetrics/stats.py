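"""Pre/post statistical battery for small paired rehabilitation cohorts.

The battery mirrors common practice in single-group pretest–post-test
pilot studies:

* a normality screen per variable (skewness in (−2, 2), excess kurtosis in
  (−4, 4), Shapiro–Wilk) routing to parametric or non-parametric tests —
  when the screen fails, the parametric result is still computed and
  reported alongside the Wilcoxon result;
* dependent (paired) t tests for planned comparisons, with Cohen's d with
  Hedges' small-sample correction and a noncentral-t 95% CI;
* exact Wilcoxon signed-rank tests (generating-function enumeration with
  mid-ranks for ties up to n = 25; normal approximation with continuity
  correction above);
* a two-way fully-within-subject repeated-measures ANOVA (e.g. intensity
  band × session phase) with Mauchly's sphericity test and
  Greenhouse–Geisser correction, reporting partial η²;
* a within-subject MANOVA (Pillai's trace) over difference scores for
  multi-subscale standardized tests (e.g. four QUEST sub-domains × time).

The user-facing entry point follows the model/results idiom:
:class:`CohortAnalysis` is built from a wide per-(child, phase) table and
its :meth:`~CohortAnalysis.fit` returns a :class:`CohortResults` carrying
every test, a rendered group-summary table with significance flags, and
plotting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io_formats
from .io_formats import CohortTable

__all__ = [
    "StatConfig",
    "StatTestResult",
    "describe",
    "normality_screen",
    "paired_t",
    "wilcoxon_signed_rank",
    "rm_anova_within",
    "manova_pillai_within",
    "hedges_g_paired",
    "CohortAnalysis",
    "CohortResults",
    "analyze_cohort",
]


@dataclass(frozen=True)
class StatConfig:
    """Thresholds and conventions shared across the battery."""

    alpha: float = 0.05
    trend_alpha: float = 0.1
    skew_bounds: tuple[float, float] = (-2.0, 2.0)
    kurtosis_bounds: tuple[float, float] = (-4.0, 4.0)
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.trend_alpha < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.skew_bounds[0] >= self.skew_bounds[1]:
            raise ValueError("skew bounds must be ordered")
        if self.kurtosis_bounds[0] >= self.kurtosis_bounds[1]:
            raise ValueError("kurtosis bounds must be ordered")

    def effect_size_label(self, g: float) -> str:
        a = abs(g)
        if a >= 0.8:
            return "large"
        if a >= 0.5:
            return "medium"
        if a >= 0.2:
            return "small"
        return "negligible"


@dataclass
class StatTestResult:
    """One test: statistic, df, p, effect size with CI, assumption report."""

    test_name: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    effect_size: float | None = None
    effect_size_type: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    assumptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# descriptives and the normality screen


def describe(values: Sequence[float]) -> dict[str, float]:
    """Mean, SE, median, IQR, bias-adjusted skewness and excess kurtosis.

    SE uses the n−1 sample SD; quartiles use linear interpolation; the
    skewness/kurtosis statistics are the small-sample bias-adjusted
    versions (excess kurtosis: normal = 0).
    """
    x = np.asarray(list(values), dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("describe requires n >= 2")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    sd = float(np.std(x, ddof=1))
    out = {
        "n": n,
        "mean": float(np.mean(x)),
        "se": sd / math.sqrt(n),
        "sd": sd,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }
    if sd == 0:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        out["skewness"] = float(sps.skew(x, bias=False))
        out["kurtosis"] = float(sps.kurtosis(x, fisher=True, bias=False))
    return out


def normality_screen(
    values: Sequence[float], config: StatConfig = StatConfig()
) -> dict[str, object]:
    """Route a variable to parametric or non-parametric analysis.

    Non-parametric iff skewness leaves ``config.skew_bounds``, excess
    kurtosis leaves ``config.kurtosis_bounds``, or Shapiro–Wilk rejects at
    ``config.alpha``.  All three diagnostics are returned.  A constant
    sample trivially passes (zero skew/kurtosis, Shapiro–Wilk undefined).
    """
    x = np.asarray(list(values), dtype=float)
    if len(x) < 3:
        raise ValueError("normality screen requires n >= 3")
    d = describe(x)
    if d["sd"] == 0:
        return {
            "decision": "parametric", "skewness": 0.0, "kurtosis": 0.0,
            "shapiro_w": float("nan"), "shapiro_p": float("nan"),
        }
    w, p = sps.shapiro(x)
    skew_ok = config.skew_bounds[0] < d["skewness"] < config.skew_bounds[1]
    kurt_ok = config.kurtosis_bounds[0] < d["kurtosis"] < config.kurtosis_bounds[1]
    shapiro_ok = p >= config.alpha
    return {
        "decision": "parametric" if (skew_ok and kurt_ok and shapiro_ok) else "nonparametric",
        "skewness": d["skewness"],
        "kurtosis": d["kurtosis"],
        "shapiro_w": float(w),
        "shapiro_p": float(p),
    }


# ---------------------------------------------------------------------------
# paired comparisons


def paired_t(
    pre: Sequence[float], post: Sequence[float], config: StatConfig = StatConfig()
) -> StatTestResult:
    """Dependent t test on d = pre − post (two-tailed), with Hedges g."""
    pre = np.asarray(list(pre), float)
    post = np.asarray(list(post), float)
    if len(pre) != len(post):
        raise ValueError("paired t requires equal lengths")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    d = pre - post
    sd = np.std(d, ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # no change anywhere: t = 0, p = 1 by convention
            return StatTestResult("paired_t", 0.0, n - 1, 1.0, 0.0, "hedges_g", 0.0, 0.0)
        raise ValueError("zero variance of differences")
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    g, lo, hi = _hedges_g_from_diffs(d, config.ci_level)
    return StatTestResult("paired_t", t, n - 1, float(p), g, "hedges_g", lo, hi)


def hedges_g_paired(
    pre: Sequence[float], post: Sequence[float], ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Hedges-corrected paired effect size on the difference-score SD.

    g = J · mean(d)/sd(d) with J = 1 − 3/(4·df − 1), df = n − 1; the CI
    inverts the noncentral-t distribution of the paired t statistic.
    Returned on the |pre − post| change scale (positive g = change in the
    post > pre direction for outcomes that improve).
    """
    d = np.asarray(list(post), float) - np.asarray(list(pre), float)
    g, lo, hi = _hedges_g_from_diffs(d, ci_level)
    return g, lo, hi


def _hedges_g_from_diffs(d: np.ndarray, ci_level: float) -> tuple[float, float, float]:
    n = len(d)
    df = n - 1
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("zero variance of differences")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    dz = float(np.mean(d)) / sd
    g = j * dz
    t_obs = dz * math.sqrt(n)
    tail = (1.0 - ci_level) / 2.0
    lo_nc = _nct_invert(t_obs, df, 1.0 - tail)
    hi_nc = _nct_invert(t_obs, df, tail)
    return g, j * lo_nc / math.sqrt(n), j * hi_nc / math.sqrt(n)


def _nct_invert(t_obs: float, df: int, prob: float) -> float:
    """Noncentrality δ with P(T_{df,δ} ≤ t_obs) = prob, by bisection."""
    lo, hi = t_obs - 50 - 10 * abs(t_obs), t_obs + 50 + 10 * abs(t_obs)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if sps.nct.cdf(t_obs, df, mid) > prob:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def wilcoxon_signed_rank(
    pre: Sequence[float], post: Sequence[float]
) -> StatTestResult:
    """Wilcoxon signed-rank test on paired data (two-sided).

    Zero differences are dropped; ties receive mid-ranks.  For n ≤ 25
    retained pairs the null distribution of W⁺ is enumerated exactly via
    its generating function over doubled ranks (so mid-ranks stay
    integral); larger samples use the normal approximation with tie
    correction and continuity correction.
    """
    d = np.asarray(list(pre), float) - np.asarray(list(post), float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    total = n * (n + 1) / 2.0
    stat = min(w_plus, total - w_plus)
    if n <= 25:
        p = _wilcoxon_exact_two_sided(ranks, w_plus)
        method = "exact"
    else:
        mu = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(z)
        method = "normal_approx"
    return StatTestResult(
        "wilcoxon_signed_rank", stat, float(n), min(1.0, float(p)),
        assumptions={"method": method, "n_nonzero": n, "w_plus": w_plus},
    )


def _wilcoxon_exact_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p: P(W⁺ ≤ w) + P(W⁺ ≥ S − w) for w = min tail.

    Enumerates the distribution of W⁺ (uniform over 2ⁿ sign patterns) by
    polynomial multiplication over doubled ranks, which keeps mid-ranks
    (k + 0.5) integral.
    """
    doubled = np.rint(2 * ranks).astype(int)
    max_sum = int(doubled.sum())
    dist = np.zeros(max_sum + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: max_sum + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * min(w_plus, ranks.sum() - w_plus)))
    lower = dist[: w2 + 1].sum()
    upper = dist[max_sum - w2 :].sum()
    return float(min(1.0, lower + upper))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (two-way, fully within-subject)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k × (k−1) orthonormal contrast matrix (normalized Helmert)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _mauchly(z: np.ndarray, alpha: float) -> dict[str, float]:
    """Mauchly's sphericity test and Greenhouse–Geisser ε on contrast
    scores ``z`` (subjects × p)."""
    n, p = z.shape
    if p == 1:
        return {"W": 1.0, "chi2": 0.0, "df": 0.0, "p": 1.0, "gg_epsilon": 1.0, "violated": False}
    s = np.cov(z, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    mean_eig = eig.mean()
    gg = float(eig.sum() ** 2 / (p * np.sum(eig**2))) if np.sum(eig**2) > 0 else 1.0
    if np.any(eig <= 0) or mean_eig == 0:
        return {"W": 0.0, "chi2": float("inf"), "df": p * (p + 1) / 2 - 1, "p": 0.0,
                "gg_epsilon": gg, "violated": True}
    w = float(np.prod(eig) / mean_eig**p)
    dof = p * (p + 1) / 2.0 - 1.0
    f = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * f * math.log(w)
    pval = float(sps.chi2.sf(chi2, dof))
    return {"W": w, "chi2": float(chi2), "df": dof, "p": pval,
            "gg_epsilon": gg, "violated": pval < alpha}


def rm_anova_within(
    data: np.ndarray,
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
    config: StatConfig = StatConfig(),
) -> dict[str, StatTestResult]:
    """Two-way fully-within-subject ANOVA on ``data[subject, a, b]``.

    Returns results for both main effects and the interaction.  Each
    effect carries Mauchly's W/p and the Greenhouse–Geisser ε on its own
    contrast scores; when Mauchly rejects at ``config.alpha``, the
    reported df and p are GG-corrected (the uncorrected df stay in the
    assumption report).  Effect sizes are partial η².
    """
    y = np.asarray(data, float)
    if y.ndim != 3:
        raise ValueError("data must be (subjects, a_levels, b_levels)")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells in within-subject layout")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")

    grand = y.mean()
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_ab = y.mean(axis=0)
    mean_s = y.mean(axis=(1, 2))
    mean_sa = y.mean(axis=2)
    mean_sb = y.mean(axis=1)

    ss_a = n * b * np.sum((mean_a - grand) ** 2)
    ss_b = n * a * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((mean_sa - mean_s[:, None] - mean_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((mean_sb - mean_s[:, None] - mean_b[None, :] + grand) ** 2)
    resid = (
        y
        - mean_sa[:, :, None]
        - mean_sb[:, None, :]
        - mean_ab[None, :, :]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        + mean_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    effects = {
        factor_names[0]: (ss_a, a - 1, ss_as, (a - 1) * (n - 1), y.mean(axis=2) @ ca),
        factor_names[1]: (ss_b, b - 1, ss_bs, (b - 1) * (n - 1), y.mean(axis=1) @ cb),
        f"{factor_names[0]}*{factor_names[1]}": (
            ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1),
            np.einsum("sab,ai,bj->sij", y, ca, cb).reshape(n, -1),
        ),
    }

    out: dict[str, StatTestResult] = {}
    for name, (ss_eff, df_eff, ss_err, df_err, z) in effects.items():
        sphericity = _mauchly(z, config.alpha)
        if ss_err == 0:
            f_stat, p = (0.0, 1.0) if ss_eff == 0 else (float("inf"), 0.0)
            df_pair = (float(df_eff), float(df_err))
        else:
            f_stat = (ss_eff / df_eff) / (ss_err / df_err)
            eps = sphericity["gg_epsilon"] if sphericity["violated"] else 1.0
            df_pair = (df_eff * eps, df_err * eps)
            p = float(sps.f.sf(f_stat, *df_pair))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out[name] = StatTestResult(
            f"rm_anova[{name}]", float(f_stat), df_pair, p,
            float(eta), "partial_eta_sq",
            assumptions={
                "mauchly_w": sphericity["W"], "mauchly_p": sphericity["p"],
                "gg_epsilon": sphericity["gg_epsilon"],
                "gg_applied": bool(sphericity["violated"]),
                "df_uncorrected": (float(df_eff), float(df_err)),
                "ss_effect": float(ss_eff), "ss_error": float(ss_err),
            },
        )
    return out


# ---------------------------------------------------------------------------
# within-subject MANOVA via difference scores


def manova_pillai_within(
    pre_scores: np.ndarray, post_scores: np.ndarray
) -> dict[str, StatTestResult]:
    """Sub-domain × time within-subject MANOVA on difference scores.

    ``pre_scores``/``post_scores`` are subjects × k matrices (k correlated
    sub-scales measured at two time points).  The time main effect is the
    univariate F(1, n−1) on per-subject mean differences; the
    sub-domain × time interaction is a one-sample Pillai's-trace test on
    k−1 orthonormal contrasts among the difference scores, with exact
    F(k−1, n−k+1).  With k = 1 the interaction is absent and the time
    effect equals the squared paired t.
    """
    pre = np.asarray(pre_scores, float)
    post = np.asarray(post_scores, float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have identical shapes")
    if pre.ndim == 1:
        pre, post = pre[:, None], post[:, None]
    n, k = pre.shape
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than sub-domains ({k})")
    d = post - pre

    # time main effect: one-sample F on the per-subject mean difference
    m = d.mean(axis=1)
    sd = np.std(m, ddof=1)
    if sd == 0:
        f_time, p_time, eta_time = (0.0, 1.0, 0.0) if np.allclose(m, 0) else (float("inf"), 0.0, 1.0)
    else:
        t = m.mean() / (sd / math.sqrt(n))
        f_time = float(t**2)
        p_time = float(sps.f.sf(f_time, 1, n - 1))
        eta_time = f_time / (f_time + n - 1)
    out = {
        "time": StatTestResult(
            "manova[time]", f_time, (1.0, float(n - 1)), p_time,
            float(eta_time), "partial_eta_sq",
        )
    }
    if k == 1:
        return out

    c = _orthonormal_contrasts(k)
    z = d @ c  # subjects × (k−1)
    p_dim = k - 1
    zbar = z.mean(axis=0)
    s = np.cov(z, rowvar=False, ddof=1)
    if np.allclose(zbar, 0) and np.allclose(s, 0):
        t2 = 0.0
    else:
        t2 = float(n * zbar @ np.linalg.solve(s, zbar))
    pillai = t2 / (t2 + n - 1)
    df1, df2 = float(p_dim), float(n - p_dim)
    f_int = (df2 / (p_dim * (n - 1))) * t2
    p_int = float(sps.f.sf(f_int, df1, df2)) if np.isfinite(f_int) else 0.0
    out["subdomain*time"] = StatTestResult(
        "manova_pillai[subdomain*time]", float(f_int), (df1, df2), p_int,
        float(pillai), "partial_eta_sq",
        assumptions={"pillai_trace": float(pillai), "hotelling_t2": t2},
    )
    return out


# ---------------------------------------------------------------------------
# the cohort model


#: outcome → (analysis family, summary style); order defines the report
DEFAULT_OUTCOMES: Mapping[str, tuple[str, str]] = {
    "quest_dissociated": ("quest", "mean_se"),
    "quest_grasps": ("quest", "mean_se"),
    "quest_weight_bearing": ("quest", "mean_se"),
    "quest_protective_extension": ("quest", "mean_se"),
    "pct_sedentary": ("intensity", "mean_se"),
    "pct_light": ("intensity", "mean_se"),
    "pct_moderate": ("intensity", "mean_se"),
    "pct_vigorous": ("intensity", "mean_se"),
    "use_ratio": ("ratio", "mean_se"),
    "magnitude_ratio_median": ("ratio", "median_iqr"),
    "pct_independent": ("video_assist", "mean_se"),
    "pct_assisted": ("video_assist", "mean_se"),
    "pct_no_activity": ("video_assist", "mean_se"),
    "bim_unim_ratio": ("video_ratio", "mean_se"),
    "bout_rate_per_min": ("video_ratio", "mean_se"),
}

#: per-outcome planned dependent-t comparisons (a priori list)
PLANNED_COMPARISONS: tuple[str, ...] = (
    "quest_dissociated",
    "quest_grasps",
    "quest_weight_bearing",
    "quest_protective_extension",
    "pct_sedentary",
    "pct_moderate",
    "use_ratio",
    "magnitude_ratio_median",
    "pct_independent",
    "bim_unim_ratio",
    "bout_rate_per_min",
)


class CohortAnalysis:
    """Model object: the full pre/post battery over a cohort table.

    Parameters
    ----------
    cohort : CohortTable
        Wide per-(child, phase) outcome table.
    config : StatConfig
        Shared thresholds and conventions.
    planned : sequence of str, optional
        Outcome columns receiving planned dependent-t comparisons;
        defaults to :data:`PLANNED_COMPARISONS` restricted to columns
        present in the table.
    """

    def __init__(
        self,
        cohort: CohortTable,
        config: StatConfig = StatConfig(),
        planned: Sequence[str] | None = None,
    ):
        self.cohort = cohort
        self.config = config
        present = [c for c in DEFAULT_OUTCOMES if c in cohort.data.columns]
        if len({cid for cid in cohort.data["child_id"]}) < 2:
            raise ValueError("cohort analysis requires at least 2 children")
        if not present:
            raise ValueError("no recognized outcome columns in cohort table")
        self.outcomes = present
        self.planned = [
            c for c in (planned if planned is not None else PLANNED_COMPARISONS) if c in present
        ]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CohortAnalysis":
        return cls(CohortTable(df), **kwargs)

    def fit(self) -> "CohortResults":
        tests: dict[str, StatTestResult] = {}
        screens: dict[str, dict] = {}
        summaries: dict[str, dict[str, dict]] = {}

        for col in self.outcomes:
            wide = self.cohort.paired(col)
            if len(wide) < 2:
                continue
            summaries[col] = {
                "early": describe(wide["early"]), "late": describe(wide["late"])
            }
            if len(wide) >= 3:
                screens[col] = {
                    phase: normality_screen(wide[phase], self.config)
                    for phase in ("early", "late")
                }

        # omnibus within-subject models per family
        quest_cols = [c for c in self.outcomes if DEFAULT_OUTCOMES[c][0] == "quest"]
        if len(quest_cols) >= 2:
            block = self._complete_block(quest_cols)
            if block is not None and len(block[0]) > len(quest_cols):
                pre, post, _ = block
                for name, res in manova_pillai_within(pre, post).items():
                    tests[f"quest[{name}]"] = res

        for family, label in (("intensity", "intensity"), ("video_assist", "arm_use")):
            cols = [c for c in self.outcomes if DEFAULT_OUTCOMES[c][0] == family]
            if len(cols) >= 2:
                block = self._complete_block(cols)
                if block is not None:
                    pre, post, _ = block
                    y = np.stack([pre, post], axis=2)  # subjects × levels × time
                    for name, res in rm_anova_within(
                        y, (label, "time"), self.config
                    ).items():
                        tests[f"{family}[{name}]"] = res

        # planned dependent-t comparisons with non-parametric fallback
        for col in self.planned:
            wide = self.cohort.paired(col)
            if len(wide) < 2:
                continue
            early, late = wide["early"].to_numpy(), wide["late"].to_numpy()
            decision = "parametric"
            if col in screens:
                if any(s["decision"] == "nonparametric" for s in screens[col].values()):
                    decision = "nonparametric"
            try:
                t_res = paired_t(early, late, self.config)
            except ValueError:
                t_res = None
            w_res = None
            if decision == "nonparametric" or t_res is None:
                try:
                    w_res = wilcoxon_signed_rank(early, late)
                except ValueError:
                    w_res = None
            primary = w_res if (decision == "nonparametric" and w_res is not None) else t_res
            if primary is None:
                continue
            primary.assumptions.setdefault("normality_decision", decision)
            if t_res is not None and primary is not t_res:
                primary.assumptions["parametric_alongside"] = {
                    "t": t_res.statistic, "p": t_res.p_value,
                }
            tests[f"planned[{col}]"] = primary

        return CohortResults(self, tests, screens, summaries)

    def _complete_block(
        self, cols: list[str]
    ) -> tuple[np.ndarray, np.ndarray, list] | None:
        """(early, late) subject × column matrices over children with every
        column observed in both phases, or None below 3 complete children."""
        wides = {col: self.cohort.paired(col) for col in cols}
        complete = sorted(set.intersection(*(set(w.index) for w in wides.values())))
        if len(complete) < 3:
            return None
        pre = np.column_stack([wides[c].loc[complete, "early"] for c in cols])
        post = np.column_stack([wides[c].loc[complete, "late"] for c in cols])
        return pre, post, complete


def analyze_cohort(
    cohort: CohortTable,
    config: StatConfig = StatConfig(),
    planned: Sequence[str] | None = None,
) -> "CohortResults":
    """Functional wrapper: build the model and fit it."""
    return CohortAnalysis(cohort, config, planned).fit()


class CohortResults:
    """Fitted battery: every test, summaries, the rendered report."""

    def __init__(self, model: CohortAnalysis, tests, screens, summaries):
        self.model = model
        self.tests: dict[str, StatTestResult] = tests
        self.screens = screens
        self.summaries = summaries

    # -- rendering ---------------------------------------------------------

    def summary_rows(self) -> list[dict[str, object]]:
        cfg = self.model.config
        rows = []
        for col in self.model.outcomes:
            if col not in self.summaries:
                continue
            style = DEFAULT_OUTCOMES[col][1]
            cells = {}
            for phase in ("early", "late"):
                d = self.summaries[col][phase]
                if style == "median_iqr":
                    cells[phase] = io_formats.format_median_iqr(d["median"], d["q1"], d["q3"])
                else:
                    cells[phase] = io_formats.format_mean_se(d["mean"], d["se"])
            test = self.tests.get(f"planned[{col}]")
            p = test.p_value if test else float("nan")
            flag = (
                io_formats.significance_flag(p, cfg.alpha, cfg.trend_alpha) if test else ""
            )
            rows.append({
                "outcome": col,
                "early": cells["early"],
                "late": cells["late"] + (f" {flag}" if flag else ""),
                "test": test.test_name if test else "",
                "statistic": round(test.statistic, 3) if test else "",
                "p": round(p, 4) if test else "",
                "effect_size": (
                    round(test.effect_size, 3)
                    if test and test.effect_size is not None else ""
                ),
                "flag": flag,
            })
        return rows

    def summary(self) -> pd.DataFrame:
        """Group-summary table: one row per outcome, early/late cells with flags."""
        return pd.DataFrame(self.summary_rows())

    def write_report(self, path, fmt: str = "csv") -> None:
        io_formats.write_report(self.summary_rows(), path, fmt)

    def tests_frame(self) -> pd.DataFrame:
        recs = []
        for key, t in self.tests.items():
            df = t.df if isinstance(t.df, tuple) else (t.df,)
            recs.append({
                "key": key, "test": t.test_name, "statistic": t.statistic,
                "df1": df[0], "df2": df[1] if len(df) > 1 else np.nan,
                "p": t.p_value, "effect_size": t.effect_size,
                "effect_size_type": t.effect_size_type,
                "ci_low": t.ci_low, "ci_high": t.ci_high,
            })
        return pd.DataFrame(recs)

    # -- plotting ----------------------------------------------------------

    def plot_paired(self, column: str, ax=None):
        """Early→late spaghetti plot for one outcome (one line per child)."""
        import matplotlib.pyplot as plt

        wide = self.model.cohort.paired(column)
        if ax is None:
            _, ax = plt.subplots(figsize=(3.5, 4))
        for _, row in wide.iterrows():
            ax.plot([0, 1], [row["early"], row["late"]], "o-", color="0.6", alpha=0.7)
        ax.plot([0, 1], [wide["early"].mean(), wide["late"].mean()], "s-", color="C3", lw=2)
        ax.set_xticks([0, 1], ["early", "late"])
        ax.set_ylabel(column)
        return ax
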