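"""Thin convenience wrapper around off-the-shelf two-sample tests.

Per-cell summary values are compared between two groups with either
Welch's unequal-variance t test (when both samples look normal) or the
Mann-Whitney U test (otherwise) — the same convention used for reporting
group differences in organelle morphometry.  This module is a reporting
helper, not part of the measurement contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups"]


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    test: str
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def compare_groups(
    a, b, metric: str = "", test: str = "auto", normality_alpha: float = 0.05
) -> GroupComparison:
    """Compare two samples of per-cell values.

    ``test`` is ``"welch"``, ``"mannwhitney"`` or ``"auto"`` (Shapiro-Wilk
    on both samples; Welch if neither rejects normality at
    ``normality_alpha``).  NaNs are dropped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        # all values identical in both groups: no evidence of a difference
        return GroupComparison(
            metric=metric, test="degenerate", statistic=np.nan, p_value=1.0,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            median_a=float(np.median(a)), median_b=float(np.median(b)),
            n_a=int(a.size), n_b=int(b.size),
        )
    if test == "auto":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            test = "mannwhitney"  # constant sample: normality undefined
        else:
            pa = sps.shapiro(a).pvalue if a.size <= 5000 else sps.normaltest(a).pvalue
            pb = sps.shapiro(b).pvalue if b.size <= 5000 else sps.normaltest(b).pvalue
            test = "welch" if (pa > normality_alpha and pb > normality_alpha) else "mannwhitney"
    if test == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(a.size),
        n_b=int(b.size),
    )
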