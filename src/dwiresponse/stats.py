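"""Univariate statistics of the two-group study design.

Paired within-group comparisons use the Wilcoxon signed-rank test,
between-group comparisons the Mann-Whitney U test, and the ΔADC-ΔVOL
association Pearson's product-moment correlation.  Group sizes of a dozen
animals sit comfortably inside exact-enumeration range, so both rank tests
switch to their exact null distributions whenever the (tie-free) sample is
small enough — results are then reproducible to the last digit.  The exact
and asymptotic branches are delegated to scipy; this module owns the branch
selection and the degenerate-input contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import DegenerateInputError, ValidationError

#: Largest (tie-free) effective sample size handled by exact enumeration.
EXACT_N_MAX = 25


@dataclass
class TestResult:
    """Statistic, two-sided p-value, method name and whether the p-value came
    from exact enumeration (vs. a normal/t approximation)."""

    statistic: float
    p_value: float
    method: str
    exact: bool


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size != values.size


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (classic Wilcoxon convention); tied absolute
    differences receive mid-ranks.  The exact distribution is used for up to
    25 tie-free non-zero differences, otherwise a normal approximation with
    continuity correction.  All-zero differences yield the degenerate result
    p = 1 with a warning.  The statistic is W = min(W+, W-).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D of equal length")
    if x.size < 2:
        raise ValidationError("at least 2 pairs required")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "wilcoxon-signed-rank", True)
    exact = d.size <= EXACT_N_MAX and not _has_ties(np.abs(d))
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", correction=True,
        method="exact" if exact else "approx",
    )
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "wilcoxon-signed-rank", exact)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact enumeration is used when the pooled sample has at most 25
    observations and no ties involving both groups; otherwise the normal
    approximation with tie correction.  The statistic reported is
    U = min(U_x, U_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    cross_tie = np.intersect1d(x, y).size > 0
    exact = (x.size + y.size) <= EXACT_N_MAX and not cross_tie and \
        not _has_ties(np.concatenate([x, y]))
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    u_x = float(res.statistic)
    u_min = min(u_x, x.size * y.size - u_x)
    return TestResult(u_min, float(min(res.pvalue, 1.0)), "mann-whitney-u", exact)


def pearson_correlation(x, y) -> TestResult:
    """Pearson product-moment correlation with a two-sided p-value from the
    t-distribution with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D of equal length")
    if x.size < 3:
        raise ValidationError("at least 3 pairs required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the inputs")
    res = scipy.stats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "pearson", False)
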