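"""Group comparisons for small lactation studies.

Kinetic and growth endpoints come in groups of 4-6 animals, far too small
for normality assumptions, so the canonical comparison is an exact
Mann-Whitney test whose p-value is obtained by complete enumeration of
group assignments.  The WSW endpoint, with more observations, uses the
unpaired Welch t test (unequal variances).  Summaries follow the
small-sample convention: median with quartiles and [min; max] range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestOutcome",
    "FiveNumber",
    "exact_mann_whitney",
    "welch_t_test",
    "median_quartiles",
    "percent_change",
]

#: Largest pooled sample size for which the exact null distribution is used.
EXACT_ENUMERATION_LIMIT = 25


@dataclass(frozen=True)
class GroupSample:
    """A labelled vector of measurements from one experimental group."""

    group: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size == 0:
            raise ValueError(f"group {self.group!r} has no values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {self.group!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TestOutcome:
    """Result of a two-sample comparison."""

    statistic: float
    p_two_sided: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 < self.p_two_sided <= 1):
            raise ValueError(f"p-value {self.p_two_sided!r} outside (0, 1]")


class FiveNumber(NamedTuple):
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


def _rank_sum_counts(doubled_ranks: list[int], n1: int) -> dict[int, dict[int, int]]:
    """Number of ways to pick k of the pooled items with a given doubled-rank sum.

    Equivalent to enumerating every C(N, n1) assignment of the pooled
    values to the first group: mid-ranks are doubled so tied (half-integer)
    ranks stay exact integers.
    """
    counts: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    counts[0][0] = 1
    for r in doubled_ranks:
        for k in range(n1, 0, -1):
            prev = counts[k - 1]
            cur = counts[k]
            for s, c in prev.items():
                cur[s + r] = cur.get(s + r, 0) + c
    return counts


def exact_mann_whitney(x: GroupSample, y: GroupSample) -> TestOutcome:
    """Two-sided Mann-Whitney U test with an exact enumerated p-value.

    For pooled sizes up to 25 the p-value is the exact proportion of the
    C(n1+n2, n1) equally likely group assignments of the observed pooled
    values whose U statistic is at least as far from the null mean
    n1*n2/2 as the observed one; ties are handled naturally because the
    enumeration operates on mid-ranks of the actual data.  Larger samples
    fall back to the tie-corrected normal approximation, flagged in the
    method label.
    """
    n1, n2 = x.n, y.n
    pooled = np.concatenate([x.values, y.values])
    if n1 + n2 > EXACT_ENUMERATION_LIMIT:
        res = sps.mannwhitneyu(x.values, y.values, alternative="two-sided",
                               method="asymptotic")
        return TestOutcome(float(res.statistic), float(res.pvalue),
                           "mann_whitney_normal_approx", n1, n2)

    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    doubled = [int(round(2 * r)) for r in ranks]
    u_doubled = sum(doubled[:n1]) - n1 * (n1 + 1)  # 2*U1
    center = n1 * n2  # 2 * n1*n2/2
    observed_dist = abs(u_doubled - center)

    counts = _rank_sum_counts(doubled, n1)[n1]
    total = math.comb(n1 + n2, n1)
    assert sum(counts.values()) == total
    extreme = sum(c for s, c in counts.items()
                  if abs(s - n1 * (n1 + 1) - center) >= observed_dist)
    return TestOutcome(u_doubled / 2.0, extreme / total, "mann_whitney_exact", n1, n2)


def welch_t_test(x: GroupSample, y: GroupSample) -> TestOutcome:
    """Unpaired two-sided t test without assuming equal variances.

    Uses the Welch statistic with Welch-Satterthwaite degrees of freedom.
    Degenerate zero-variance inputs are resolved explicitly: equal means
    give p = 1, separated means give p -> 0.
    """
    if x.n < 2 or y.n < 2:
        raise ValueError("Welch test needs at least 2 observations per group")
    v1, v2 = x.values.var(ddof=1), y.values.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.values.mean() == y.values.mean():
            return TestOutcome(0.0, 1.0, "welch_t", x.n, y.n)
        return TestOutcome(math.inf, np.nextafter(0, 1), "welch_t", x.n, y.n)
    res = sps.ttest_ind(x.values, y.values, equal_var=False)
    return TestOutcome(float(res.statistic), float(res.pvalue), "welch_t", x.n, y.n)


def welch_satterthwaite_df(x: GroupSample, y: GroupSample) -> float:
    """Effective degrees of freedom of the Welch statistic."""
    a = x.values.var(ddof=1) / x.n
    b = y.values.var(ddof=1) / y.n
    return (a + b) ** 2 / (a**2 / (x.n - 1) + b**2 / (y.n - 1))


def median_quartiles(values) -> FiveNumber:
    """Median, quartiles (linear interpolation) and range of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return FiveNumber(float(med), float(q1), float(q3), float(v.min()), float(v.max()))


def percent_change(reference: float, value: float) -> float:
    """Relative change of ``value`` versus ``reference``, in percent."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (value - reference) / reference
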