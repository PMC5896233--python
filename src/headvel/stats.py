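"""Shared statistical primitives used across the analysis modules.

Thin, opinionated wrappers around scipy: a two-sided Fisher exact test by
the probability-mass rule, a Pearson chi-square on 2x2 tables without
continuity correction, and a paired Wilcoxon signed-rank test that uses the
exact null for small samples and degrades gracefully on all-zero
differences instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["fisher_exact", "chi_square", "paired_wilcoxon", "WilcoxonResult"]


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Exact two-sided p by summing the probabilities of all tables (with the
    observed margins) whose hypergeometric probability does not exceed the
    observed table's.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("table entries must be non-negative integers")
        table = table.astype(int)
    return float(sps.fisher_exact(table, alternative="two-sided").pvalue)


def chi_square(table):
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table.

    Returns ``(statistic, p_value)``.  Degenerate margins (an all-zero row
    or column) are rejected.
    """
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margins: zero row or column total")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    degenerate: bool = False


def paired_wilcoxon(x, y=None, exact_below: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences are discarded (Wilcoxon's rule).  With fewer than
    ``exact_below`` informative pairs the exact null distribution is used,
    otherwise the normal approximation with tie correction.  If every
    difference is zero the test is degenerate: p = 1, flagged.
    """
    d = np.asarray(x, float) - (0.0 if y is None else np.asarray(y, float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0,
                              degenerate=True)
    # exact method requires untied |d|; fall back to the approximation on ties
    has_ties = np.unique(np.abs(d)).size < n
    if n < exact_below and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(d, alternative="two-sided", zero_method="wilcox",
                       method=method)
    return WilcoxonResult(statistic=float(res.statistic),
                          p_value=float(res.pvalue), n_effective=int(n))
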