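"""Statistical toolkit for compartment-resolved neuronal quantification.

Implements the normality-gated testing scheme used throughout the analyses:
Shapiro-Wilk decides between the parametric branch (one-way/multiway ANOVA with
Tukey HSD) and the nonparametric branch (Kruskal-Wallis with Dunn's post hoc
and Holm correction), plus effect sizes (eta squared and its H-based analogue),
Benjamini-Hochberg adjustment, Fisher's exact gene-set overlap, rank-sum group
comparison and bootstrap estimation statistics.

All group tests accept sequences of 1-D numeric arrays. Results are returned as
:class:`StatResult` records so downstream tables carry the test name, statistic,
degrees of freedom, raw and adjusted p values, and the effect size together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "normality_gate",
    "oneway_anova",
    "multiway_anova_main_effects",
    "tukey_hsd",
    "kruskal_wallis",
    "dunn_holm",
    "bh_adjust",
    "holm_adjust",
    "fisher_overlap",
    "bootstrap_mean_diff",
    "rank_sum",
]


@dataclass
class StatResult:
    """One hypothesis test: statistic, df, p values and effect size."""

    test: str
    statistic: float
    df: tuple[float, ...] = ()
    p: float = float("nan")
    p_adjusted: float = float("nan")
    adjust_method: str | None = None
    eta_squared: float = float("nan")
    extra: dict = field(default_factory=dict)


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    out = [g[~np.isnan(g)] for g in out]
    if any(len(g) == 0 for g in out):
        raise ValueError("empty group")
    return out


def normality_gate(groups, alpha: float = 0.05) -> str:
    """Choose the test branch from per-group Shapiro-Wilk normality tests.

    Returns ``"nonparametric"`` if any group rejects normality at ``alpha``
    (or is too small / degenerate for the test), otherwise ``"parametric"``.
    """
    groups = _as_groups(groups)
    for g in groups:
        if len(g) < 3:
            warnings.warn("group with n < 3; falling back to nonparametric branch")
            return "nonparametric"
        if np.ptp(g) == 0:
            warnings.warn("degenerate (constant) group; nonparametric branch")
            return "nonparametric"
        if sps.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def oneway_anova(groups) -> StatResult:
    """One-way fixed-effects ANOVA with eta squared = SS_between / SS_total."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total == 0:
        return StatResult("oneway_anova", float("nan"), extra={"degenerate": True})
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_between
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else float("inf")
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return StatResult(
        "oneway_anova", float(f), (df_b, df_w), p, eta_squared=ss_between / ss_total
    )


def multiway_anova_main_effects(response, factors: pd.DataFrame) -> dict[str, StatResult]:
    """Main-effects ANOVA (Type-I sequential SS) for one or more crossed factors.

    ``factors`` is a table of categorical columns aligned with ``response``.
    Returns one :class:`StatResult` per factor with F, p and eta squared
    (factor SS over total SS). No interaction terms are fitted.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(response, dtype=float)
    if len(factors) != len(y):
        raise ValueError("response and factor table lengths differ")
    names = list(factors.columns)
    # alias check: two factors with identical groupings cannot be separated
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if factors.groupby(a, observed=True)[b].nunique().max() == 1 and (
                factors.groupby(b, observed=True)[a].nunique().max() == 1
            ):
                raise ValueError(f"aliased factors: {a!r} and {b!r}")
    df = factors.copy()
    df["_y"] = y
    formula = "_y ~ " + " + ".join(f"C({c})" for c in names)
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(fit, typ=1)
    ss_total = float(tab["sum_sq"].sum())
    out: dict[str, StatResult] = {}
    for c in names:
        row = tab.loc[f"C({c})"]
        out[c] = StatResult(
            "anova_main_effect",
            float(row["F"]),
            (float(row["df"]), float(tab.loc["Residual", "df"])),
            float(row["PR(>F)"]),
            eta_squared=float(row["sum_sq"]) / ss_total,
        )
    return out


def tukey_hsd(groups) -> list[StatResult]:
    """Tukey HSD pairwise comparisons (studentized range) after one-way ANOVA."""
    groups = _as_groups(groups)
    res = sps.tukey_hsd(*groups)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out.append(
                StatResult(
                    "tukey_hsd",
                    float(res.statistic[i, j]),
                    p=float(res.pvalue[i, j]),
                    p_adjusted=float(res.pvalue[i, j]),
                    adjust_method="tukey",
                    extra={"pair": (i, j)},
                )
            )
    return out


def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis H (tie-corrected, reported on the chi-squared scale).

    The effect size is the H-based eta squared
    ``eta2_H = (H - k + 1) / (n - k)`` for k groups and n total observations.
    """
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = sum(len(g) for g in groups)
    k = len(groups)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return StatResult("kruskal_wallis", 0.0, (k - 1,), 1.0, eta_squared=0.0)
    h, p = sps.kruskal(*groups)
    eta2 = (h - k + 1) / (n - k) if n > k else float("nan")
    return StatResult("kruskal_wallis", float(h), (k - 1,), float(p), eta_squared=float(eta2))


def _dunn_z(groups) -> tuple[np.ndarray, list[tuple[int, int]]]:
    # Dunn's z on mean ranks with tie correction over the pooled sample
    allv = np.concatenate(groups)
    n = len(allv)
    ranks = sps.rankdata(allv)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12 * (n - 1))) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    zs, pairs = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            zs.append(z)
            pairs.append((i, j))
    return np.asarray(zs), pairs


def dunn_holm(groups) -> list[StatResult]:
    """Dunn's post hoc pairwise z tests with Holm step-down adjustment."""
    groups = _as_groups(groups)
    zs, pairs = _dunn_z(groups)
    raw = 2 * sps.norm.sf(np.abs(zs))
    adj = holm_adjust(raw)
    return [
        StatResult(
            "dunn",
            float(z),
            p=float(pr),
            p_adjusted=float(pa),
            adjust_method="holm",
            extra={"pair": pair},
        )
        for z, pr, pa, pair in zip(zs, raw, adj, pairs)
    ]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def fisher_overlap(set_a_size: int, set_b_size: int, overlap: int, background_size: int) -> StatResult:
    """Fisher's exact test for the overlap of two gene sets on a background.

    The 2x2 table is ``a = overlap``, ``b = |A| - a``, ``c = |B| - a``,
    ``d = N - |A| - |B| + a``. Returns the sample odds ratio ``ad / bc`` and the
    two-sided hypergeometric p value.
    """
    a, A, B, N = overlap, set_a_size, set_b_size, background_size
    if not (0 <= a <= min(A, B) <= max(A, B) <= N):
        raise ValueError("inconsistent overlap counts")
    b, c, d = A - a, B - a, N - A - B + a
    if d < 0:
        raise ValueError("background smaller than the union of the sets")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return StatResult("fisher_overlap", float(odds), p=float(p), extra={"table": (a, b, c, d)})


def bootstrap_mean_diff(group_a, group_b, n_boot: int = 5000, seed: int = 0, ci: float = 0.95):
    """Bootstrapped mean difference (A - B) with a percentile confidence interval.

    Resamples within each group with replacement; deterministic under ``seed``.
    Returns ``(observed_diff, (lo, hi))``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        diffs[i] = rng.choice(a, len(a)).mean() - rng.choice(b, len(b)).mean()
    tail = (1 - ci) / 2
    lo, hi = np.quantile(diffs, [tail, 1 - tail])
    return float(a.mean() - b.mean()), (float(lo), float(hi))


def rank_sum(group_a, group_b, exact_max_n: int = 25) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and there are no ties, and the tie-corrected
    normal approximation (no continuity correction) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and max(len(a), len(b)) <= exact_max_n) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return StatResult("rank_sum", float(res.statistic), (len(a), len(b)), float(min(res.pvalue, 1.0)),
                      extra={"method": method})
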