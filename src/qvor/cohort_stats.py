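"""Cohort-level descriptive and inferential statistics.

Mirrors the analyses a clinical normative study runs on a healthy cohort:
per-measure summaries overall and stratified by sex or decade age bins,
Kolmogorov-Smirnov normality screening, a one-sample Wilcoxon signed-rank
test of the achieved oscillation frequency against the 0.75 Hz metronome
target, an independent-samples t-test between sexes, Levene homogeneity +
one-way ANOVA across age groups, and linear-interpolation percentile tables.

All tests are thin, validated wrappers over scipy.stats so results match the
field-standard implementations; every function is deterministic given its
input vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "CohortSummary",
    "TestResult",
    "AGE_BINS",
    "age_bin_label",
    "summarize_cohort",
    "test_normality",
    "test_frequency_vs_target",
    "compare_groups",
    "anova_by_groups",
    "compute_percentiles",
    "PERCENTILE_LEVELS",
]

PERCENTILE_LEVELS = (5, 10, 25, 50, 75, 90, 95)

#: Decade age bins: <=20, 21-30, ..., 71-80, >80 (upper bound inclusive).
AGE_BINS = ((0, 20), (21, 30), (31, 40), (41, 50), (51, 60), (61, 70),
            (71, 80), (81, np.inf))


def age_bin_label(age: float) -> str:
    for lo, hi in AGE_BINS:
        if lo <= age <= hi:
            if lo == 0:
                return "<=20"
            if np.isinf(hi):
                return ">80"
            return f"{lo}-{hi}"
    raise ValidationError(f"age {age} outside supported bins")


@dataclass
class CohortSummary:
    """n/mean/sd/min/max of one measure within one group."""

    measure: str
    group: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass
class TestResult:
    """Outcome of one inferential test."""

    test: str
    statistic: float
    p_value: float
    effect: float = np.nan
    group_sizes: tuple = ()
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value must lie in [0, 1]")


def summarize_cohort(
    df: pd.DataFrame,
    measures: Sequence[str],
    group_by: str | None = None,
) -> list[CohortSummary]:
    """Descriptive summaries per measure, overall or grouped.

    ``group_by`` may be None, ``"sex"``, or ``"age"`` (decade bins).
    Sample SD (ddof=1) is reported; NaN for groups of one.
    """
    if df.empty:
        raise ValidationError("empty cohort")
    work = df.copy()
    if group_by is None:
        work["_group"] = "overall"
    elif group_by == "sex":
        work["_group"] = work["sex"].astype(str)
    elif group_by == "age":
        work["_group"] = work["age"].map(age_bin_label)
    else:
        raise ValidationError(f"unsupported group_by {group_by!r}")

    out: list[CohortSummary] = []
    for group, sub in work.groupby("_group", sort=True):
        for measure in measures:
            vals = pd.to_numeric(sub[measure], errors="coerce").dropna().to_numpy()
            if vals.size == 0:
                continue
            out.append(
                CohortSummary(
                    measure=measure,
                    group=str(group),
                    n=int(vals.size),
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    min=float(vals.min()),
                    max=float(vals.max()),
                )
            )
    return out


def test_normality(values: Iterable[float]) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample sd).

    Parameters are estimated from the data (the common clinical-software
    usage), which makes the test conservative relative to Lilliefors.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 5:
        raise InsufficientDataError("normality test needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult("ks_normality", 0.0, 0.0, degenerate=True,
                          note="zero variance", group_sizes=(x.size,))
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult("ks_normality", float(stat), float(p),
                      group_sizes=(x.size,))


def test_frequency_vs_target(
    frequencies: Iterable[float], target: float = 0.75, *, method: str = "wilcoxon"
) -> TestResult:
    """Is the achieved oscillation frequency shifted from the metronome target?

    Default is the one-sample Wilcoxon signed-rank test on
    ``frequency - target`` (frequencies are typically non-normal);
    ``method="ttest"`` gives the one-sample Student's t alternative.
    If every difference is zero the result is degenerate (no rejection).
    """
    x = np.asarray(list(frequencies), dtype=float)
    if x.size < 6:
        raise InsufficientDataError("frequency comparison needs n >= 6")
    diffs = x - target
    effect = float(diffs.mean())
    if np.allclose(diffs, 0.0):
        return TestResult(f"frequency_{method}", 0.0, 1.0, effect=effect,
                          group_sizes=(x.size,), degenerate=True,
                          note="all frequencies equal the target")
    if method == "wilcoxon":
        stat, p = stats.wilcoxon(diffs)
    elif method == "ttest":
        stat, p = stats.ttest_1samp(x, target)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return TestResult(f"frequency_{method}", float(stat), float(p),
                      effect=effect, group_sizes=(x.size,))


def compare_groups(
    values: Iterable[float],
    labels: Iterable,
    *,
    equal_var: bool = True,
) -> TestResult:
    """Two-sample t-test between the two label groups.

    Effect is reported as ``mean(group2) - mean(group1)`` with groups taken
    in sorted label order, so e.g. F/M labels give the male-minus-female mean
    difference.  ``equal_var=False`` switches to Welch.
    """
    x = np.asarray(list(values), dtype=float)
    lab = np.asarray(list(labels))
    uniq = sorted(set(lab.tolist()))
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {len(uniq)}")
    g1 = x[lab == uniq[0]]
    g2 = x[lab == uniq[1]]
    if min(g1.size, g2.size) < 2:
        raise InsufficientDataError("both groups need n >= 2")
    effect = float(g2.mean() - g1.mean())
    if np.allclose(g1, g1.mean()) and np.allclose(g2, g2.mean()) and effect == 0.0:
        return TestResult("ttest_ind", 0.0, 1.0, effect=0.0,
                          group_sizes=(g1.size, g2.size), degenerate=True,
                          note="identical groups")
    stat, p = stats.ttest_ind(g2, g1, equal_var=equal_var)
    return TestResult("ttest_ind", float(stat), float(p), effect=effect,
                      group_sizes=(int(g1.size), int(g2.size)))


def anova_by_groups(
    values: Iterable[float], labels: Iterable
) -> tuple[TestResult, TestResult]:
    """Levene homogeneity check followed by one-way ANOVA across groups.

    Post hoc comparisons are the caller's decision and only warranted when
    the ANOVA rejects.
    """
    x = np.asarray(list(values), dtype=float)
    lab = np.asarray(list(labels))
    groups = [x[lab == u] for u in sorted(set(lab.tolist()))]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValidationError("need >= 2 groups with n >= 2 each")
    sizes = tuple(int(g.size) for g in groups)
    lev_stat, lev_p = stats.levene(*groups, center="mean")
    f_stat, f_p = stats.f_oneway(*groups)
    return (
        TestResult("levene", float(lev_stat), float(lev_p), group_sizes=sizes),
        TestResult("anova_oneway", float(f_stat), float(f_p), group_sizes=sizes),
    )


def compute_percentiles(
    values: Iterable[float], levels: Sequence[float] = PERCENTILE_LEVELS
) -> dict[float, float]:
    """Linear-interpolation percentiles of a sample, non-decreasing in level."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise InsufficientDataError("percentiles need n >= 2")
    pct = np.percentile(x, levels, method="linear")
    return {float(lv): float(p) for lv, p in zip(levels, pct)}
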