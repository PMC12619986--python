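"""Group-level statistical comparisons and cohort summaries.

Implements the study's statistical plan: Mann–Whitney rank-sum tests for
independent groups (unaffected vs. DM1), Wilcoxon matched-pairs signed-rank
tests for paired pre/post comparisons, and two-way ANOVA (independent or
repeated-measures) with Šídák-adjusted pairwise post hoc comparisons for
group × titration-state designs. Summaries report mean and sample SD over
non-missing values; p-values in [0.05, 0.1) are labelled trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "summarize",
    "compare_independent",
    "compare_paired",
    "sidak_adjust",
    "two_way_anova_sidak",
    "label_significance",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple


def label_significance(p: float, alpha: float = 0.05, trend_band: float = 0.1) -> str:
    """'significant' below alpha, 'trend' in [alpha, trend_band), else 'ns'."""
    if p < alpha:
        return "significant"
    if p < trend_band:
        return "trend"
    return "ns"


def summarize(table: pd.DataFrame, column: str, group: str | None = None):
    """Mean, sample SD (n-1 denominator) and n over non-missing values.

    Missing entries are excluded; a single non-missing value yields an
    undefined (NaN) SD. Raises when every value is missing.
    """
    sub = table if group is None else table[table["group"] == group]
    vals = pd.to_numeric(sub[column], errors="coerce").dropna()
    if vals.empty:
        raise ValueError(f"column {column!r} has no non-missing values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return mean, sd, len(vals)


def compare_independent(group_a, group_b) -> TestResult:
    """Two-sided Mann–Whitney rank-sum test for independent groups.

    Exact enumeration of the rank-sum distribution when the combined sample
    is small (n ≤ 12) and tie-free; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one value")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"mann-whitney-{method}",
        n=(a.size, b.size),
    )


def compare_paired(pre, post) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are discarded (standard Wilcoxon convention); if every
    difference is zero the comparison is degenerate and p = 1 by convention.
    Exact null enumeration over sign assignments for n ≤ 15 without tied
    |differences|; normal approximation otherwise.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    d = b[mask] - a[mask]
    if d.size == 0:
        raise ValueError("no complete pairs")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return TestResult(0.0, 1.0, "wilcoxon-degenerate", (d.size, d.size))
    no_ties = np.unique(np.abs(nonzero)).size == nonzero.size
    method = "exact" if (nonzero.size <= 15 and no_ties) else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon-{method}",
        n=(d.size, d.size),
    )


def sidak_adjust(p: float, k: int) -> float:
    """Šídák multiple-comparison adjustment: ``1 - (1 - p)**k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(1.0 - (1.0 - p) ** k)


def two_way_anova_sidak(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    state: str = "state",
    subject: str | None = None,
    repeated: bool = False,
) -> dict:
    """Two-way ANOVA with Šídák-adjusted per-state pairwise comparisons.

    ``data`` is long format with a numeric ``value`` column and two
    categorical factors (``group``, e.g. cohort arm or timepoint, and
    ``state``, e.g. titration state). With ``repeated=True`` both factors are
    within-subject (``subject`` required and the design must be complete:
    every subject measured in every group × state cell). Post hoc pairwise
    comparisons contrast the two group levels within each state via t-tests
    (paired in the repeated case) and adjust with ``1 - (1 - p)**k`` where k
    is the number of states compared.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = data[[value, group, state] + ([subject] if subject else [])].copy()
    df = df.dropna(subset=[value])
    levels = sorted(df[group].unique())
    if len(levels) != 2:
        raise ValueError("expected exactly two group levels for pairwise contrasts")
    states = sorted(df[state].unique())

    if repeated:
        if subject is None:
            raise ValueError("repeated design requires a subject column")
        counts = df.groupby([subject, group, state]).size().unstack([group, state])
        if counts.isna().any().any() or (counts != 1).any().any():
            raise ValueError(
                "repeated-measures design is incomplete: every subject needs "
                "exactly one value per group x state cell"
            )
        from statsmodels.stats.anova import AnovaRM
        fit = AnovaRM(df, depvar=value, subject=subject, within=[group, state]).fit()
        anova = fit.anova_table
    else:
        model = ols(f"{value} ~ C({group}) * C({state})", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)

    k = len(states)
    rows = []
    for st in states:
        a = df[(df[state] == st) & (df[group] == levels[0])]
        b = df[(df[state] == st) & (df[group] == levels[1])]
        if repeated:
            merged = a.merge(b, on=subject, suffixes=("_a", "_b"))
            res = stats.ttest_rel(merged[f"{value}_a"], merged[f"{value}_b"])
        else:
            res = stats.ttest_ind(a[value], b[value])
        p = float(res.pvalue)
        rows.append(
            dict(state=st, comparison=f"{levels[0]} vs {levels[1]}",
                 statistic=float(res.statistic), p_value=p,
                 p_sidak=sidak_adjust(p, k),
                 label=label_significance(sidak_adjust(p, k)))
        )
    return {"anova": anova, "pairwise": pd.DataFrame(rows), "k_comparisons": k}
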