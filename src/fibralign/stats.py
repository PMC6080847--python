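"""Group-level statistics on alignment-index tables.

The experimental design is a between-subject comparison of per-image AI
values: developmental stages are compared with a one-way ANOVA followed
by Tukey's HSD multiple-comparison test, and wounded-versus-unwounded
timecourses with per-timepoint two-sample t-tests (Welch by default).

A GroupTable is a long-format pandas DataFrame with columns
``image_id, group, timepoint, condition, ai`` (condition in
{"unwounded", "wounded"}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUP_TABLE_COLUMNS",
    "TestReport",
    "assign_stars",
    "validate_group_table",
    "summarize_groups",
    "anova_tukey",
    "wounded_vs_unwounded_ttests",
    "reports_to_frame",
]

log = logging.getLogger(__name__)

GROUP_TABLE_COLUMNS = ["image_id", "group", "timepoint", "condition", "ai"]

# significance ladder: p < 0.0001 ****, < 0.001 ***, < 0.01 **, < 0.05 *, else ns
_STAR_THRESHOLDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def assign_stars(p: float) -> str:
    """Map a p value onto the conventional significance ladder."""
    if not 0.0 <= p <= 1.0 or np.isnan(p):
        return "na"
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class TestReport:
    """One hypothesis-test result row."""

    test: str                 # "anova", "tukey", "t_welch", "t_pooled"
    comparison: str           # "omnibus" or "A vs B"
    statistic: float
    p_value: float
    stars: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.stars:
            self.stars = assign_stars(self.p_value)

    def to_dict(self) -> dict:
        return asdict(self)


def reports_to_frame(reports: list[TestReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])


def validate_group_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and AI range; returns the table (no copy)."""
    missing = [c for c in GROUP_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"group table missing columns: {missing}")
    ai = table["ai"].to_numpy(dtype=float)
    if np.any((ai < 0) | (ai > 1)):
        raise ValueError("ai values must lie in [0, 1]")
    if (table["group"].astype(str).str.len() == 0).any():
        raise ValueError("group labels must be non-empty")
    return table


def summarize_groups(table: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Per-group n, mean and sample SD (n-1 denominator).

    A singleton group has no sample SD; it is reported as NaN.
    """
    validate_group_table(table)
    if table.empty:
        raise ValueError("empty group table")
    out = (
        table.groupby(by, sort=False)["ai"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


def anova_tukey(
    table: pd.DataFrame, groups: list[str] | None = None
) -> list[TestReport]:
    """One-way ANOVA across groups plus all pairwise Tukey HSD comparisons.

    Returns the omnibus F test first, then one report per group pair with
    the family-wise adjusted p value. All-zero within-group variance is
    reported as a degenerate omnibus row instead of crashing.
    """
    validate_group_table(table)
    if groups is None:
        groups = list(table["group"].unique())
    samples = [table.loc[table["group"] == g, "ai"].to_numpy(float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups for ANOVA")
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has n < 2")

    if all(np.var(s) == 0.0 for s in samples):
        log.warning("zero within-group variance in every group; ANOVA undefined")
        return [TestReport("anova", "omnibus", float("nan"), float("nan"),
                           stars="na", degenerate=True)]

    F, p = sps.f_oneway(*samples)
    reports = [TestReport("anova", "omnibus", float(F), float(p))]
    tukey = sps.tukey_hsd(*samples)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            reports.append(
                TestReport(
                    "tukey",
                    f"{groups[i]} vs {groups[j]}",
                    float(tukey.statistic[i, j]),
                    float(tukey.pvalue[i, j]),
                )
            )
    return reports


def wounded_vs_unwounded_ttests(
    table: pd.DataFrame,
    timepoints: list[str] | None = None,
    *,
    welch: bool = True,
) -> list[TestReport]:
    """Two-sided two-sample t-test (wounded vs unwounded) per timepoint.

    Welch's unequal-variance form by default; ``welch=False`` pools. A
    timepoint missing either condition (or with n < 2) is skipped with a
    warning rather than failing the batch.
    """
    validate_group_table(table)
    if timepoints is None:
        timepoints = list(table["timepoint"].unique())
    name = "t_welch" if welch else "t_pooled"
    reports = []
    for tp in timepoints:
        sub = table[table["timepoint"] == tp]
        a = sub.loc[sub["condition"] == "wounded", "ai"].to_numpy(float)
        b = sub.loc[sub["condition"] == "unwounded", "ai"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            log.warning("timepoint %r lacks both conditions with n >= 2; skipped", tp)
            continue
        if np.array_equal(np.sort(a), np.sort(b)) and np.var(a) == 0 and np.var(b) == 0:
            # identical constant samples: t = 0, p = 1 by convention
            reports.append(TestReport(name, f"{tp}: wounded vs unwounded", 0.0, 1.0))
            continue
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
        reports.append(
            TestReport(name, f"{tp}: wounded vs unwounded", float(t), float(p))
        )
    return reports
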