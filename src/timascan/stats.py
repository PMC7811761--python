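"""Cohort-level group comparisons and correlations.

Test selection mirrors standard biostatistics practice for these data:
normally distributed variables get one-way ANOVA with Tukey's pairwise
follow-up; non-Gaussian variables get rank tests (Mann-Whitney U for two
groups, exact for small samples; Kruskal-Wallis plus pairwise Mann-Whitney
with Bonferroni for more). The normality screen is Shapiro-Wilk per group at
alpha 0.05. Bonferroni-adjusted p values are min(1, m * p) with m recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparisonResult", "CorrelationResult", "compare_groups", "correlate"]

ALPHA = 0.05
EXACT_MWU_MAX_N = 12


@dataclass
class GroupComparisonResult:
    variable: str
    groups: tuple[str, ...]
    test_used: str  # anova_tukey | mann_whitney | kruskal_wallis | t_test
    statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    n_dropped: int = 0
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


@dataclass
class CorrelationResult:
    x: str
    y: str
    method: str
    r: float
    p: float
    n: int


def _is_normalish(groups: list[np.ndarray]) -> bool:
    for g in groups:
        if len(g) >= 3 and len(np.unique(g)) > 1:
            if sps.shapiro(g).pvalue < ALPHA:
                return False
    return True


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    method = ("exact" if max(len(a), len(b)) <= EXACT_MWU_MAX_N
              and not _has_ties(a, b) else "asymptotic")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    grouping: str,
    method: str = "auto",
    n_comparisons: int | None = None,
) -> list[GroupComparisonResult]:
    """Compare a variable across diagnosis groups.

    For more than two groups, returns the omnibus result followed by pairwise
    follow-ups (Tukey after ANOVA, Bonferroni-adjusted Mann-Whitney after
    Kruskal-Wallis). Pairs where a group has fewer than two observations are
    skipped with a notice. Missing values are dropped per variable.
    """
    sub = cohort[[grouping, variable]].dropna()
    n_dropped = len(cohort) - len(sub)
    names = sorted(sub[grouping].unique())
    data = {g: sub.loc[sub[grouping] == g, variable].to_numpy(float) for g in names}
    nonempty = [g for g in names if len(data[g]) > 0]
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty groups")

    if method == "auto":
        normal = _is_normalish([data[g] for g in nonempty])
        if len(nonempty) == 2:
            method = "anova_tukey" if normal else "mann_whitney"
        else:
            method = "anova_tukey" if normal else "kruskal_wallis"

    results: list[GroupComparisonResult] = []

    def pairs() -> list[tuple[str, str]]:
        return [(a, b) for i, a in enumerate(nonempty) for b in nonempty[i + 1:]]

    if len(nonempty) == 2 or method == "mann_whitney":
        m = n_comparisons or 1
        for a, b in pairs():
            if len(data[a]) < 2 or len(data[b]) < 2:
                results.append(GroupComparisonResult(
                    variable, (a, b), method, np.nan, np.nan, np.nan, m,
                    n_dropped, note="skipped: group with < 2 observations"))
                continue
            if method == "mann_whitney":
                stat, p = _mwu(data[a], data[b])
            else:  # two-group parametric comparison
                stat, p = sps.ttest_ind(data[a], data[b])
                stat, p = float(stat), float(p)
            results.append(GroupComparisonResult(
                variable, (a, b), method, stat, p, min(1.0, m * p), m, n_dropped))
        return results

    arrays = [data[g] for g in nonempty]
    if method == "anova_tukey":
        f_stat, p_omni = sps.f_oneway(*arrays)
        results.append(GroupComparisonResult(
            variable, tuple(nonempty), "anova_tukey", float(f_stat),
            float(p_omni), float(p_omni), 1, n_dropped, note="omnibus ANOVA"))
        tukey = sps.tukey_hsd(*arrays)
        for i, a in enumerate(nonempty):
            for j in range(i + 1, len(nonempty)):
                b = nonempty[j]
                p = float(tukey.pvalue[i, j])
                results.append(GroupComparisonResult(
                    variable, (a, b), "anova_tukey",
                    float(tukey.statistic[i, j]), p, p, 1, n_dropped,
                    note="Tukey HSD (family-wise adjusted)"))
    elif method == "kruskal_wallis":
        h_stat, p_omni = sps.kruskal(*arrays)
        results.append(GroupComparisonResult(
            variable, tuple(nonempty), "kruskal_wallis", float(h_stat),
            float(p_omni), float(p_omni), 1, n_dropped,
            note="omnibus Kruskal-Wallis"))
        pw = pairs()
        m = n_comparisons or len(pw)
        for a, b in pw:
            if len(data[a]) < 2 or len(data[b]) < 2:
                results.append(GroupComparisonResult(
                    variable, (a, b), "mann_whitney", np.nan, np.nan, np.nan,
                    m, n_dropped, note="skipped: group with < 2 observations"))
                continue
            stat, p = _mwu(data[a], data[b])
            results.append(GroupComparisonResult(
                variable, (a, b), "mann_whitney", stat, p, min(1.0, m * p),
                m, n_dropped, note="pairwise after Kruskal-Wallis"))
    else:
        raise ValueError(f"unknown method {method!r}")
    return results


def correlate(
    cohort: pd.DataFrame,
    x: str,
    y: str,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlation with two-sided p; incomplete pairs dropped and n reported."""
    sub = cohort[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete pairs")
    xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = sps.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(x, y, method, float(r), float(p), len(sub))


def results_table(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """One row per comparison, exportable as CSV."""
    return pd.DataFrame([{
        "variable": r.variable,
        "groups": " vs ".join(r.groups),
        "test_used": r.test_used,
        "statistic": r.statistic,
        "p_raw": r.p_raw,
        "p_adjusted": r.p_adjusted,
        "n_comparisons": r.n_comparisons,
        "n_dropped": r.n_dropped,
        "significant": r.significant,
        "note": r.note,
    } for r in results])
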