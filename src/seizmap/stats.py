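"""Group-comparison statistics used around the pipeline.

One-way ANOVA with Dunnett's many-to-one comparison, two-way factorial
ANOVA with Sidak-adjusted pairwise contrasts, the Mantel-Cox log-rank test
for Kaplan-Meier survival curves, and a ROUT-like robust outlier screen at
FDR level Q. The alpha = 0.05 significance convention applies throughout.

Dunnett's adjustment is evaluated by seeded Monte-Carlo sampling of the
joint null distribution of the maximum |t| statistic (default 1e5 draws,
p accurate to ~+/-0.005) rather than from tabulated critical values, so
arbitrary group counts and unbalanced designs are supported.

The ROUT screen is implemented in reduced form for the constant model
(group scalars, not nonlinear regression): robust center = median, robust
scale = the 68.27th percentile of absolute residuals with a small-sample
correction, t-like scores screened by Benjamini-Hochberg at level Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats as sst

from .transcriptomics import bh_adjust

__all__ = [
    "TestResult",
    "one_way_anova",
    "dunnett",
    "two_way_anova_sidak",
    "sidak_adjust",
    "log_rank",
    "rout_outliers",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    comparisons: dict[str, float] = field(default_factory=dict)  # adjusted p per comparison


def _validate_groups(data: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {k: np.asarray(v, float) for k, v in data.items()}
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 values")
    return clean


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------

def one_way_anova(data: dict[str, list[float]]) -> TestResult:
    """Classical one-way fixed-effects F test."""
    groups = _validate_groups(data)
    values = list(groups.values())
    if all(np.var(v) == 0 for v in values):
        raise ValueError("zero within-group variance in every group; F undefined")
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_b = len(values) - 1
    df_w = sum(len(v) for v in values) - len(values)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sst.f.sf(f, df_b, df_w))
    return TestResult(statistic=float(f), df=(df_b, df_w), p_value=p)


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparison (Monte-Carlo max-|t|)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _dunnett_null_max_t(
    group_ns: tuple[int, ...], df_w: int, n_draws: int, seed: int
) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the joint Dunnett null.

    ``group_ns`` lists the control group's size first. Group means are
    drawn N(0, 1/n_g) from one independent substream per group (so adding
    a group leaves the other groups' draws unchanged); the pooled SD comes
    from a uniform substream mapped through the chi-square quantile, which
    reuses the same draws across designs with different residual df.
    Cached: repeated calls with the same design are free.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(group_ns) + 1)
    z = [
        np.random.default_rng(children[i + 1]).standard_normal(n_draws) / np.sqrt(ng)
        for i, ng in enumerate(group_ns)
    ]
    u = np.random.default_rng(children[0]).random(n_draws)
    s_null = np.sqrt(sst.chi2.ppf(u, df_w) / df_w)
    max_t = np.zeros(n_draws)
    n0 = group_ns[0]
    for i, ng in enumerate(group_ns[1:], start=1):
        t_g = np.abs(z[i] - z[0]) / (s_null * np.sqrt(1 / ng + 1 / n0))
        np.maximum(max_t, t_g, out=max_t)
    max_t.setflags(write=False)
    return max_t


def dunnett(
    data: dict[str, list[float]],
    control_group: str,
    n_draws: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Compare each group to the control; family-wise adjusted p-values.

    The observed statistics are many-to-one t statistics on the pooled
    within-group variance. Adjustment: the null distribution of
    max_i |T_i| is sampled by Monte-Carlo (``n_draws`` draws, seeded), and
    each comparison's adjusted p is P(max |T| >= |t_i|). The group-mean
    draws use one independent substream per group so that adding a group
    leaves the other groups' draws unchanged.
    """
    groups = _validate_groups(data)
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not present")
    others = [g for g in groups if g != control_group]
    ctrl = groups[control_group]

    n = {g: len(v) for g, v in groups.items()}
    df_w = sum(n.values()) - len(groups)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    if ss_within == 0:
        raise ValueError("zero pooled within-group variance")
    s2 = ss_within / df_w

    t_obs = {
        g: (groups[g].mean() - ctrl.mean()) / np.sqrt(s2 * (1 / n[g] + 1 / n[control_group]))
        for g in others
    }

    max_t = _dunnett_null_max_t(
        tuple(n[g] for g in [control_group] + others), df_w, n_draws, seed
    )
    comparisons = {
        g: float(np.mean(max_t >= abs(t_obs[g]))) for g in others
    }
    worst = min(comparisons.values())
    return TestResult(
        statistic=float(max(abs(t) for t in t_obs.values())),
        df=(float(len(others)), float(df_w)),
        p_value=worst,
        comparisons=comparisons,
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA with Sidak-adjusted comparisons
# ---------------------------------------------------------------------------

def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m."""
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("need p in [0,1] and m >= 1")
    return float(1.0 - (1.0 - p) ** m)


def two_way_anova_sidak(
    data: pd.DataFrame,
    comparisons: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> TestResult:
    """Two-way factorial ANOVA with Sidak-adjusted cell-mean comparisons.

    ``data`` needs columns ``factor1, factor2, value`` forming a complete
    factorial layout. ``comparisons`` lists pairs of (factor1, factor2)
    cells; each is a t test on cell means against the ANOVA MSE, adjusted
    by Sidak with m = number of comparisons. The returned statistic/p are
    those of the interaction term; main-effect results ride along in
    ``comparisons`` under ``F[factor1]``/``F[factor2]`` keys.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    need = {"factor1", "factor2", "value"}
    if not need <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(need)}")
    cells = data.groupby(["factor1", "factor2"], observed=True)["value"]
    counts = cells.count()
    full = len(data["factor1"].unique()) * len(data["factor2"].unique())
    if len(counts) < full or (counts < 1).any():
        raise ValueError("incomplete factorial layout (empty cells)")

    model = ols("value ~ C(factor1) * C(factor2)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = "C(factor1):C(factor2)"
    df_resid = float(model.df_resid)
    mse = float(model.mse_resid)

    extra: dict[str, float] = {
        "F[factor1]": float(table.loc["C(factor1)", "PR(>F)"]),
        "F[factor2]": float(table.loc["C(factor2)", "PR(>F)"]),
    }
    if comparisons:
        m = len(comparisons)
        means = cells.mean()
        for (c1, c2) in comparisons:
            n1, n2 = counts[c1], counts[c2]
            t = (means[c1] - means[c2]) / np.sqrt(mse * (1 / n1 + 1 / n2))
            p_raw = 2 * float(sst.t.sf(abs(t), df_resid))
            extra[f"{c1} vs {c2}"] = sidak_adjust(p_raw, m)

    return TestResult(
        statistic=float(table.loc[inter, "F"]),
        df=(float(table.loc[inter, "df"]), df_resid),
        p_value=float(table.loc[inter, "PR(>F)"]),
        comparisons=extra,
    )


# ---------------------------------------------------------------------------
# Log-rank (Mantel-Cox)
# ---------------------------------------------------------------------------

def log_rank(records: pd.DataFrame, group_a: str, group_b: str) -> TestResult:
    """Mantel-Cox log-rank test between two survival groups.

    ``records`` needs columns ``group, day, event`` (event 1 = death,
    0 = censored at that day).
    """
    sub = records[records["group"].isin([group_a, group_b])]
    if sub["event"].sum() == 0:
        raise ValueError("no events in either group")
    a = sub[sub["group"] == group_a]
    b = sub[sub["group"] == group_b]
    res = logrank_test(
        a["day"], b["day"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return TestResult(
        statistic=float(res.test_statistic), df=(1.0,), p_value=float(res.p_value)
    )


# ---------------------------------------------------------------------------
# ROUT-like outlier screen
# ---------------------------------------------------------------------------

def rout_outliers(values, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Simplified ROUT outlier screen for the constant model.

    Residuals from the median are scaled by the robust SD (68.27th
    percentile of |residuals|, corrected by n/(n-1)); the resulting t-like
    scores get two-sided t(n-1) p-values screened by Benjamini-Hochberg at
    FDR level ``q``. Returns (clean_values, outliers).
    """
    x = np.asarray(values, float)
    if len(x) < 5:
        raise ValueError("need at least 5 values")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * len(x) / (len(x) - 1)
    if rsdr == 0:
        return x.copy(), np.array([])
    t_scores = np.abs(resid) / rsdr
    p = 2.0 * sst.t.sf(t_scores, df=len(x) - 1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    flagged = bh_adjust(p) < q
    return x[~flagged], x[flagged]
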