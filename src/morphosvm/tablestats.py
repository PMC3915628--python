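"""Cohort-table statistics and inverse reconstruction of confusion matrices.

Covers the tests reported in case-control demographic tables: the Pearson
chi-square for 2x2 categorical splits (no continuity correction — the
variant that reproduces the published statistics from the printed counts),
the pooled two-sample t test computed from summary statistics, and the
Mann-Whitney U test.  `reconstruct_confusion` inverts printed, rounded
sensitivity/specificity percentages back to the unique integer contingency
table they came from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .crossval import ConfusionMatrix

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "chi_square_2x2",
    "two_sample_t",
    "mann_whitney",
    "reconstruct_confusion",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) for group 1 yes/no and (c, d) for group 2 yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str  # "chi2" | "t_pooled" | "mann_whitney"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-square for a 2x2 table, df = 1.

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), equivalently the
    squared phi coefficient times n.  No continuity correction by default.
    A zero marginal makes the statistic undefined; it is reported as 0 with
    a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    marg = (a + b) * (c + d) * (a + c) * (b + d)
    if marg == 0:
        warnings.warn("zero marginal: chi-square defined as 0", stacklevel=2)
        return TestResult(statistic=0.0, df=1, p_value=1.0, method="chi2")
    dev = abs(a * d - b * c)
    if continuity_correction:
        dev = max(dev - n / 2.0, 0.0)
    chi2 = n * dev**2 / marg
    return TestResult(
        statistic=float(chi2),
        df=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        method="chi2",
    )


def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample t test from summary statistics.

    df = n1 + n2 - 2; two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    return TestResult(
        statistic=float(t),
        df=df,
        p_value=float(2.0 * stats.t.sf(abs(t), df=df)),
        method="t_pooled",
    )


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Exact p for samples of 8 or fewer (no ties); tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    exact = max(x.size, y.size) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(min(res.pvalue, 1.0)),
        method="mann_whitney",
    )


def reconstruct_confusion(
    n_pos: int,
    n_neg: int,
    printed_sens_pct: float,
    printed_spec_pct: float,
    tolerance_pct: float = 0.05,
) -> ConfusionMatrix:
    """Invert printed sensitivity/specificity percentages to integer counts.

    Brute-force search over tp in [0, n_pos] and tn in [0, n_neg] for counts
    whose exact percentages fall within ``tolerance_pct`` of the printed
    values.  The default 0.05 covers pure half-up rounding to one decimal;
    tables that truncate instead of round need 0.1.  Raises if no count
    matches; warns and returns the closest if several do.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one subject per class")
    if tolerance_pct < 0.05:
        raise ValueError("tolerance below printing precision (0.05)")

    def matches(count: int, n: int, printed: float) -> bool:
        return abs(100.0 * count / n - printed) <= tolerance_pct + 1e-12

    tps = [tp for tp in range(n_pos + 1) if matches(tp, n_pos, printed_sens_pct)]
    tns = [tn for tn in range(n_neg + 1) if matches(tn, n_neg, printed_spec_pct)]
    if not tps:
        raise ValueError(
            f"no tp in [0, {n_pos}] yields sensitivity {printed_sens_pct}% "
            f"within {tolerance_pct} points"
        )
    if not tns:
        raise ValueError(
            f"no tn in [0, {n_neg}] yields specificity {printed_spec_pct}% "
            f"within {tolerance_pct} points"
        )
    if len(tps) > 1 or len(tns) > 1:
        warnings.warn(
            f"ambiguous reconstruction: tp candidates {tps}, tn candidates "
            f"{tns}; returning the closest match",
            stacklevel=2,
        )
    tp = min(tps, key=lambda v: abs(100.0 * v / n_pos - printed_sens_pct))
    tn = min(tns, key=lambda v: abs(100.0 * v / n_neg - printed_spec_pct))
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)
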