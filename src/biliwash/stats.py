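"""Contingency-table and repeated-measures statistics.

Implements the tests applied to exchange-transfusion safety and efficacy
data: the uncorrected Pearson χ² and the Fisher exact test on 2×2 tables of
adverse events (first vs second hour of the procedure), one-way
within-subjects (repeated-measures) ANOVA for serial laboratory values, and
two-sample t statistics.

Design notes
------------
* No Yates continuity correction: the plain Pearson statistic is what the
  2×2 tables in this setting are reported with.
* The two-sided Fisher p is the sum of hypergeometric probabilities no
  larger than that of the observed table, conditional on the margins — the
  most common convention.  Probabilities are exact rationals (math.comb),
  so the "≤ observed" comparison involves no floating-point tolerance.
* Tail probabilities for χ², F and t come from the regularized incomplete
  gamma/beta functions (scipy.special), accurate to well below 1e−8.
* No sphericity correction is applied to the repeated-measures F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "ContingencyTable2x2",
    "RepeatedMeasuresData",
    "TestResult",
    "AnovaResult",
    "ZeroMarginError",
    "chi2_2x2",
    "chi2_2x2_test",
    "fisher_exact_2x2",
    "rm_anova_F",
    "two_sample_t",
    "chi2_sf",
    "f_sf",
    "t_two_sided_p",
]


class ZeroMarginError(ValueError):
    """Pearson χ² is undefined: a row or column margin is zero."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Event/no-event counts in the first vs second half of a procedure.

    Rows are periods, columns are outcome::

                   event   no event
        first half   a        b
        second half  c        d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("grand total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | tuple | None = None


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_time: int
    df_error: int
    p_value: float
    ss_time: float
    ss_subject: float
    ss_error: float


def chi2_sf(x: float, df: float) -> float:
    """Upper tail of the χ² distribution, P(X ≥ x)."""
    if x < 0:
        return 1.0
    return float(special.gammaincc(df / 2.0, x / 2.0))


def f_sf(x: float, df1: float, df2: float) -> float:
    """Upper tail of the F distribution, P(X ≥ x)."""
    if x <= 0:
        return 1.0
    return float(special.betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * x)))


def t_two_sided_p(t: float, df: float) -> float:
    """Two-sided p for a t statistic: P(|T| ≥ |t|)."""
    if t == 0:
        return 1.0
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


def chi2_2x2(table: ContingencyTable2x2) -> float:
    """Uncorrected Pearson χ² statistic: n(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)].

    Undefined when any margin is zero — use :func:`fisher_exact_2x2` there.
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise ZeroMarginError(
            "chi-square is undefined for a zero margin; use the Fisher exact test"
        )
    a, b, c, d = table.a, table.b, table.c, table.d
    num = table.n * (a * d - b * c) ** 2
    return num / (r1 * r2 * c1 * c2)


def chi2_2x2_test(table: ContingencyTable2x2) -> TestResult:
    """Pearson χ² test (1 df) on a 2×2 table."""
    stat = chi2_2x2(table)
    return TestResult(stat, chi2_sf(stat, 1.0), df=1)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Conditional on both margins, enumerates every table (the first cell a
    ranges over its feasible interval) and sums the hypergeometric
    probabilities that do not exceed the observed table's.  Degenerate
    margins (only one table possible) give p = 1.
    """
    r1, _, c1, _ = table.margins
    n = table.n
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    if lo == hi:
        return 1.0
    denom = math.comb(n, c1)
    # comb(r1, a) * comb(r2, c1-a) is the unnormalized hypergeometric weight
    weights = [math.comb(r1, a) * math.comb(n - r1, c1 - a) for a in range(lo, hi + 1)]
    w_obs = weights[table.a - lo]
    p = Fraction(sum(w for w in weights if w <= w_obs), denom)
    return min(float(p), 1.0)


@dataclass(frozen=True)
class RepeatedMeasuresData:
    """A complete subjects × timepoints measurement matrix."""

    values: np.ndarray
    timepoints_min: Sequence[float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D subjects × timepoints matrix")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 timepoints")
        if not np.all(np.isfinite(v)):
            raise ValueError("missing or non-finite cells are not supported")
        if self.timepoints_min is not None and len(self.timepoints_min) != v.shape[1]:
            raise ValueError("timepoint labels do not match the number of columns")


def rm_anova_F(data: RepeatedMeasuresData | np.ndarray) -> AnovaResult:
    """One-way within-subjects ANOVA F statistic for the time effect.

    Classical decomposition: the between-subjects sum of squares is removed,
    and F = MS_time / MS_error with df = (T−1, (T−1)(S−1)).
    """
    if not isinstance(data, RepeatedMeasuresData):
        data = RepeatedMeasuresData(np.asarray(data))
    y = data.values
    s, t = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    ss_time = s * float(np.sum((time_means - grand) ** 2))
    ss_subj = t * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    ss_err = ss_total - ss_time - ss_subj
    df_time = t - 1
    df_err = (t - 1) * (s - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        if ss_time == 0:
            return AnovaResult(0.0, df_time, df_err, 1.0, 0.0, ss_subj, 0.0)
        raise ZeroDivisionError(
            "degenerate repeated-measures data: zero error variance"
        )
    f = (ss_time / df_time) / ms_err
    return AnovaResult(f, df_time, df_err, f_sf(f, df_time, df_err), ss_time, ss_subj, ss_err)


def two_sample_t(x, y, paired: bool = False) -> TestResult:
    """Two-sample t statistic, sign convention mean(x) − mean(y).

    Unpaired uses the pooled-variance (equal-variance) form; paired uses the
    one-sample t on the differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            raise ZeroDivisionError("paired differences have zero variance")
        df = len(d) - 1
        t = d.mean() / (sd / math.sqrt(len(d)))
    else:
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        if sp2 == 0:
            raise ZeroDivisionError("samples have zero pooled variance")
        df = nx + ny - 2
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return TestResult(float(t), t_two_sided_p(float(t), df), df=df)
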