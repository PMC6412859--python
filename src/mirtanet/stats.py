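"""Shared statistical primitives.

Unequal-variance (Welch) two-sample t-tests — in raw-data and
summary-statistic form — and the signed fold-change transform used to
report log2 expression ratios as linear multiples.

The group sizes throughout this kind of study are tiny (n = 2–6), so
p-values always come from the exact t distribution with
Welch–Satterthwaite degrees of freedom, never a normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "welch_t_test",
    "welch_t_test_from_summary",
    "signed_fold_change",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD summary of one group, as printed in results tables."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError("mean must be finite")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ValueError("sd must be finite and >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    """Two-sided Welch test result.

    ``degenerate`` is set when both groups had zero variance, in which
    case the p-value is 1 (equal means) or 0 (unequal means) by
    convention.
    """

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    degenerate: bool = False


def _degenerate_result(mean_a: float, mean_b: float, n_a: int, n_b: int) -> TestResult:
    df = float(n_a + n_b - 2)
    if mean_a == mean_b:
        return TestResult(0.0, df, 1.0, degenerate=True)
    t = math.inf if mean_a > mean_b else -math.inf
    return TestResult(t, df, 0.0, degenerate=True)


def welch_t_test(sample_a, sample_b) -> TestResult:
    """Two-tailed two-sample unequal-variance Student's t-test.

    Parameters
    ----------
    sample_a, sample_b
        Sequences of at least 2 finite values each.

    Returns
    -------
    TestResult
        Welch statistic, Welch–Satterthwaite degrees of freedom and the
        two-sided p-value from the exact t distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must contain only finite values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return _degenerate_result(float(a.mean()), float(b.mean()), a.size, b.size)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def welch_t_test_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Welch test computed directly from mean/SD/n summaries.

    Identical formulas to :func:`welch_t_test`; lets printed
    mean ± SD tables be tested without the raw data.
    """
    if a.sd == 0.0 and b.sd == 0.0:
        return _degenerate_result(a.mean, b.mean, a.n, b.n)
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    # Welch-Satterthwaite df in scale-invariant ratio form (scipy does
    # not return df for the stats form)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    r = va / (va + vb)
    df = 1.0 / (r**2 / (a.n - 1) + (1.0 - r) ** 2 / (b.n - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue))


def signed_fold_change(log2_ratio: float) -> float:
    """Convert a log2 expression ratio to a signed linear fold change.

    sign(L) * 2**|L|, so a halving (L = −1) is reported as −2.0 and no
    change (L = 0) as +1.0. Down-regulation thus appears as a negative
    multiple, matching how fold changes are printed in expression
    tables.
    """
    L = float(log2_ratio)
    if not math.isfinite(L):
        raise ValueError("log2 ratio must be finite")
    if L == 0.0:
        return 1.0
    return math.copysign(2.0 ** abs(L), L)
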