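"""Descriptive group-comparison statistics and multiple-testing helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats as sps

__all__ = [
    "mann_whitney",
    "chi_squared",
    "percent_summary",
    "median_mad",
    "bonferroni",
]


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact enumeration for small samples (both n <= 20), normal approximation
    with tie correction otherwise.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (x.size <= 20 and y.size <= 20) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_squared(table, df: int | None = None) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction.

    ``df`` defaults to the table's (r-1)(c-1); passing it asserts the table
    shape matches the declared degrees of freedom.
    """
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    if df is not None and df != dof:
        raise ValueError(f"table implies {dof} df, but {df} requested")
    return float(stat), float(p)


def percent_summary(n_sub: int, n_group: int) -> float:
    """Percentage 100 n_sub / n_group with half-up rounding to 1 decimal.

    Matches the printed-table convention of rounding at two decimals before
    the final one-decimal figure (so 62.048 -> 62.05 -> 62.1).
    """
    if n_group <= 0:
        raise ValueError("group size must be positive")
    if not 0 <= n_sub <= n_group:
        raise ValueError("subgroup count must be within [0, group size]")
    pct = Decimal(100 * n_sub) / Decimal(n_group)
    two = pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(two.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def median_mad(x) -> tuple[float, float]:
    """Median and unscaled median absolute deviation.

    Missing values are excluded; an all-missing sample is an error.  No
    normal-consistency constant is applied.
    """
    arr = np.asarray(x, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no non-missing values")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return med, mad


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("test count must be >= 1")
    return alpha / m
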