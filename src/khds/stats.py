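"""Discrimination and association statistics.

The central quantity is the c statistic (area under the ROC curve): the
probability that a randomly chosen outcome-positive subject scores higher
than a randomly chosen outcome-negative one, with tied pairs counting
one-half (the Mann-Whitney convention — load-bearing here, since a 4-level
score makes ties ubiquitous).  Its standard error uses the Hanley-McNeil
closed form, which depends only on the c statistic A and the counts of
positive and negative subjects:

    Q1 = A / (2 - A)
    Q2 = 2 A^2 / (1 + A)
    SE = sqrt[ (A(1-A) + (n_pos-1)(Q1 - A^2) + (n_neg-1)(Q2 - A^2))
               / (n_pos * n_neg) ]

Two c statistics are compared by a normal z test on their difference,
z = (A1 - A2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2), with r = 0 for
independent samples; a user-supplied correlation r handles comparisons on
the same patients.  The reported p is the one-tailed probability
P(Z >= |z|); the sign of the difference is reported separately.

Association tests are the classical ones: Yates-continuity-corrected
chi-squared for 2x2 tables (uncorrected Pearson for wider tables), and the
pooled-variance two-sample Student's t test.

Not provided: DeLong variance estimation, exact or bootstrap AUC confidence
intervals, multiple-testing correction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class UndefinedDiscriminationError(ValueError):
    """All outcomes positive or all negative: the c statistic is undefined."""


class DegenerateComparisonError(ValueError):
    """Both standard errors are zero: the z comparison is undefined."""


class ComparisonMethod(enum.Enum):
    INDEPENDENT = "independent"
    PAIRED = "paired"


@dataclass(frozen=True)
class ROCResult:
    """A c statistic with its Hanley-McNeil standard error."""

    auc: float
    se: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"auc must be in [0, 1], got {self.auc}")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must each be >= 1")
        if self.se < 0:
            raise ValueError("se must be >= 0")


@dataclass(frozen=True)
class AUCComparison:
    """Difference of two c statistics with its z score and one-tailed p."""

    delta: float
    z: float
    p: float


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p: float
    yates_applied: bool


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form standard error of a c statistic.

    Parameters
    ----------
    auc
        The c statistic A, in [0, 1].
    n_pos, n_neg
        Counts of outcome-positive and outcome-negative subjects (each >= 1).

    The SE is exactly 0 at A = 0 or A = 1.
    """
    if not (0.0 <= auc <= 1.0):
        raise ValueError(f"auc must be in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must each be >= 1")
    a2 = auc * auc
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * a2 / (1.0 + auc)
    num = auc * (1.0 - auc) + (n_pos - 1) * (q1 - a2) + (n_neg - 1) * (q2 - a2)
    # rounding can push the numerator a hair below zero at A in {0, 1}
    return math.sqrt(max(num, 0.0) / (n_pos * n_neg))


def c_statistic(scores, outcomes) -> ROCResult:
    """Concordance probability of a score for a binary outcome.

    A = (# positive-negative pairs where the positive scores higher
         + 0.5 x tied pairs) / (n_pos x n_neg),

    computed via midranks, so ordinal scores with heavy ties are handled
    exactly.  Invariant under any strictly increasing transform of the
    scores.

    Raises
    ------
    UndefinedDiscriminationError
        If outcomes are all positive or all negative.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-d and the same length")
    y = y.astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedDiscriminationError(
            f"need both outcome classes (n_pos={n_pos}, n_neg={n_neg})"
        )
    ranks = sps.rankdata(s)  # midranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    auc = min(max(float(auc), 0.0), 1.0)
    return ROCResult(auc=auc, se=hanley_mcneil_se(auc, n_pos, n_neg), n_pos=n_pos, n_neg=n_neg)


def compare_c_statistics(
    r1: ROCResult,
    r2: ROCResult,
    method: ComparisonMethod | str = ComparisonMethod.INDEPENDENT,
    corr: float = 0.0,
) -> AUCComparison:
    """z test on the difference of two c statistics.

    ``method="independent"`` uses r = 0; ``method="paired"`` uses the
    supplied correlation ``corr`` between the two estimates (comparisons on
    the same patients are positively correlated, so the independent test is
    conservative).  p is the one-tailed upper-tail normal probability
    P(Z >= |z|); equal c statistics give z = 0, p = 0.5.
    """
    method = ComparisonMethod(method)
    r = corr if method is ComparisonMethod.PAIRED else 0.0
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"correlation must be in [0, 1], got {r}")
    var = r1.se**2 + r2.se**2 - 2.0 * r * r1.se * r2.se
    delta = r1.auc - r2.auc
    if var <= 0.0:
        raise DegenerateComparisonError("zero variance of the AUC difference")
    z = delta / math.sqrt(var)
    p = float(sps.norm.sf(abs(z)))
    return AUCComparison(delta=delta, z=z, p=p)


def yates_chi2(table) -> ContingencyResult:
    """Chi-squared test of a 2x2 table with Yates' continuity correction.

    chi2 = n (|ad - bc| - n/2)^2 / [(a+b)(c+d)(a+c)(b+d)], df = 1.
    The correction is clamped: |ad - bc| <= n/2 gives chi2 = 0.

    Raises
    ------
    ValueError
        On a non-2x2 table, negative counts, or a zero margin.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("all row and column margins must be > 0")
    diff = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * diff**2 / math.prod(margins)
    p = float(sps.chi2.sf(chi2, df=1))
    return ContingencyResult(chi2=float(chi2), df=1, p=p, yates_applied=True)


def chi2_test(table) -> ContingencyResult:
    """Yates-corrected chi-squared for 2x2 tables; uncorrected Pearson for
    wider tables (e.g. score 0-3 x outcome)."""
    t = np.asarray(table, dtype=float)
    if t.shape == (2, 2):
        return yates_chi2(t)
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(chi2=float(chi2), df=int(df), p=float(p), yates_applied=False)


def student_t(sample1, sample2) -> TTestResult:
    """Pooled-variance two-sample Student's t test, two-sided p."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample must have size >= 2")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=int(x.size + y.size - 2), p=float(res.pvalue))
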