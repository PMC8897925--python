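"""Small statistical helpers used across the integration modules.

All chi-square tests in this package are Pearson tests without continuity
correction; correlation p-values come from the exact t-distribution
transform with n-2 degrees of freedom (scipy's ``pearsonr``).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Equals the closed form n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    Raises ValueError on a zero margin.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def chi2_contingency_nocorr(table) -> tuple[float, float, int]:
    """Pearson chi-square on an r x c table, dropping all-zero rows/columns.

    Returns (statistic, p, dof). Raises ValueError if fewer than two
    non-empty rows or columns remain.
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("degenerate contingency table")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p), int(dof)


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson r with its two-sided p-value; raises on n < 3 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs for a correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the correlated columns")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size)
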