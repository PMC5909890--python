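"""Closed-form statistics: Hanley-McNeil SE and independent-ROC z-test,
chi-square tests, and two-sample t-tests.

The Hanley-McNeil standard error of a ROC AUC ``A`` estimated from
``n_A`` cases and ``n_N`` controls is

    SE(A) = sqrt[ (A(1-A) + (n_A-1)(Q1-A^2) + (n_N-1)(Q2-A^2)) / (n_A n_N) ]

with Q1 = A/(2-A) and Q2 = 2A^2/(1+A). Two AUCs from independent
samples are compared with z = (A1-A2)/sqrt(SE1^2+SE2^2), two-tailed
p from the standard normal distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


def mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney U statistic (ties counted 1/2).

    Equals the probability that a randomly chosen case scores above a
    randomly chosen control, with ties contributing half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(scores)  # midranks handle ties
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def hanley_mcneil_se(auc: float, n_cases: int, n_controls: int) -> float:
    """Hanley-McNeil standard error of an AUC.

    >>> round(hanley_mcneil_se(0.791, 27, 36), 4)
    0.0597
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("group counts must be >= 1")
    a2 = auc * auc
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * a2 / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n_cases - 1) * (q1 - a2) + (n_controls - 1) * (q2 - a2)) / (
        n_cases * n_controls
    )
    return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class ROCComparison:
    """z/p comparison of two independent ROC AUCs (H0: equal AUCs)."""

    auc1: float
    auc2: float
    se1: float
    se2: float
    z: float
    p: float

    @property
    def conclusion(self) -> str:
        return "reject_H0" if self.p < ALPHA else "accept_H0"


def compare_independent_rocs(roc1, roc2) -> ROCComparison:
    """Hanley-McNeil z-test between two independent ROC results.

    Arguments may be :class:`~mzpanel.evaluation.ROCResult` objects or
    any objects carrying ``auc``, ``n_cases`` and ``n_controls``.
    """
    se1 = hanley_mcneil_se(roc1.auc, roc1.n_cases, roc1.n_controls)
    se2 = hanley_mcneil_se(roc2.auc, roc2.n_cases, roc2.n_controls)
    denom = math.hypot(se1, se2)
    if denom == 0.0:
        z = 0.0 if roc1.auc == roc2.auc else math.inf * math.copysign(1, roc1.auc - roc2.auc)
    else:
        z = (roc1.auc - roc2.auc) / denom
    p = 2.0 * (1.0 - sps.norm.cdf(abs(z))) if math.isfinite(z) else 0.0
    p = min(max(p, 0.0), 1.0)
    return ROCComparison(auc1=roc1.auc, auc2=roc2.auc, se1=se1, se2=se2, z=z, p=p)


def chisq_gof(counts, proportions) -> tuple[float, int, float]:
    """Pearson goodness-of-fit test against expected proportions.

    >>> chi2, df, p = chisq_gof([26, 5], [0.5, 0.5])
    >>> round(chi2, 2)
    14.23
    """
    counts = np.asarray(counts, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    if counts.shape != proportions.shape:
        raise ValueError("counts and proportions must have the same length")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if not math.isclose(proportions.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    expected = counts.sum() * proportions
    if (expected == 0).any():
        raise ValueError("expected count of zero")
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = len(counts) - 1
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def chisq_2x2(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table.

    Continuity correction off by default (``yates=True`` enables it).

    >>> chi2, df, p = chisq_2x2([[22, 16], [26, 5]])
    >>> round(chi2, 2)
    5.44
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row, col = t.sum(axis=1), t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(row, col) / t.sum()
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, 1))
    return chi2, 1, p


def two_sample_t(x, y, welch: bool = True) -> tuple[float, float, float]:
    """Independent two-sample t-test (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if float(x.mean()) == float(y.mean()):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(x) + len(y) - 2)
    return float(res.statistic), df, float(res.pvalue)
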