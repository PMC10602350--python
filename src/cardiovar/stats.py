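"""Normality-routed two-sample comparisons and simple correlation.

Group differences are tested with Student's t-test when both samples pass a
Shapiro-Wilk normality check (alpha = 0.05 per group), and with the two-sided
Mann-Whitney U test otherwise.  Results with p < 0.05 are flagged
significant.  The routing gate is applied per group; the t-test assumes equal
variances by default (a ``equal_var`` switch exposes Welch's form).  No
multiple-testing correction is applied by default; Holm step-down is
available as an option for users comparing many parameters at once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "correlate", "holm_correct"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    test_name: str            # 't_test' or 'mann_whitney'
    statistic: float
    p_value: float
    significant: bool
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0, 1]")


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # Shapiro-Wilk is undefined for constant samples
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue >= alpha


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample comparison routed by per-group Shapiro-Wilk normality."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples contain non-finite values")

    both_normal = _is_normal(a, normality_alpha) and _is_normal(b, normality_alpha)
    degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
    if both_normal and not degenerate:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test_name = "t_test"
    else:
        if degenerate:
            logger.warning("zero-variance samples: routing to Mann-Whitney U")
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test_name = "mann_whitney"
    p = float(res.pvalue)
    if not np.isfinite(p):  # e.g. all values tied
        p = 1.0
    return GroupComparison(
        test_name=test_name,
        statistic=float(res.statistic),
        p_value=p,
        significant=p < alpha,
        n_a=a.size,
        n_b=b.size,
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def holm_correct(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float).ravel()
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
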