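"""Group-level statistics: mean +/- SD of per-patient percentages and
one-way ANOVA across fertility groups.

The unit of analysis is the patient: each patient contributes one
percentage per category (their clone patterns summarised), and groups are
compared on those per-patient percentages. With two groups the one-way
ANOVA F equals the square of the pooled-variance t statistic, so pairwise
comparisons are reported through the same machinery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats as sps

__all__ = ["GroupComparison", "mean_sd", "one_way_anova", "significance_stars"]

ALPHA = 0.05


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator).

    With a single value the SD is undefined; 0.0 is returned (the
    degenerate case is flagged by callers that care about n).
    """
    n = len(values)
    if n == 0:
        raise ValueError("mean_sd of empty sequence")
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA of one metric across >= 2 groups."""

    metric: str
    group_labels: tuple[str, ...]
    group_n: tuple[int, ...]
    group_mean: tuple[float, ...]
    group_sd: tuple[float, ...]
    anova_F: float
    df_between: int
    df_within: int
    p_value: float
    significant: bool
    degenerate: bool = False  # zero within-group variance with nonzero between


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    metric: str = "",
    alpha: float = ALPHA,
) -> GroupComparison:
    """One-way fixed-effects ANOVA from between/within sums of squares.

    F = (SS_between / (k-1)) / (SS_within / (N-k)); p is the upper tail of
    the F(k-1, N-k) distribution. If every group is internally constant but
    the group means differ, F is +inf and p = 0, flagged as degenerate.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    labels = tuple(labels) if labels is not None else tuple(f"g{i+1}" for i in range(k))
    ns = tuple(len(g) for g in groups)
    N = sum(ns)
    means = tuple(sum(g) / len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / N
    ss_between = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ss_within = sum(sum((x - m) ** 2 for x in g) for g, m in zip(groups, means))
    df_between = k - 1
    df_within = N - k
    degenerate = False
    if ss_within == 0:
        if ss_between > 0:
            F, p = math.inf, 0.0
            degenerate = True
        else:
            F, p = 0.0, 1.0
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(F, df_between, df_within))
    sds = tuple(mean_sd(g)[1] for g in groups)
    return GroupComparison(
        metric=metric,
        group_labels=labels,
        group_n=ns,
        group_mean=means,
        group_sd=sds,
        anova_F=F,
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        significant=p < alpha,
        degenerate=degenerate,
    )


def significance_stars(p: float) -> str:
    """Figure-legend style marks: * for p<0.05, ** for p<0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
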