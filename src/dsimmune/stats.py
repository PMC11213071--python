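"""Shared statistical primitives.

Every analysis stage in this package reduces to a small set of tests and
robust summaries: Fisher's exact test on 2x2 positivity tables,
Benjamini-Hochberg FDR control, Mann-Whitney U for unpaired group
comparisons, the paired Wilcoxon signed-rank test for trial time courses,
and interquartile-range based extreme-outlier masking.

Conventions fixed here (and used consistently downstream):

* all tests are two-sided;
* odds ratios get the Haldane-Anscombe +0.5 correction when any cell of the
  2x2 table is zero, so effect sizes stay finite;
* quantiles use linear interpolation (quantile index = p*(n-1));
* "extreme outlier" means strictly beyond Q1 - 3*IQR or Q3 + 3*IQR;
* Wilcoxon drops zero differences and flags the degenerate all-zero case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_exact",
    "benjamini_hochberg",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "quartiles",
    "extreme_outlier_mask",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``effect`` is an odds ratio for Fisher's test and a median difference
    for the rank tests (unpaired: difference of group medians; paired:
    median of paired differences).
    """

    statistic: float
    p_value: float
    effect: float
    method: str
    exact: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.size != 4:
        raise ValueError("a 2x2 table requires exactly four counts")
    arr = arr.reshape(2, 2)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    if arr.sum() == 0:
        raise ValueError("table total must be positive")
    return arr


def odds_ratio_2x2(table) -> float:
    """Sample odds ratio a*d / (b*c), Haldane-Anscombe corrected.

    When any cell is zero, 0.5 is added to every cell so the estimate is
    finite in enrichment screens with empty cells.
    """
    t = _as_2x2(table)
    if np.any(t == 0):
        t = t + 0.5
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Rows are groups, columns positive/negative. The two-sided p-value sums
    hypergeometric probabilities of all tables (with the observed margins)
    no more probable than the observed one.
    """
    t = _as_2x2(table)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        statistic=float(t[0, 0]),
        p_value=float(min(p, 1.0)),
        effect=odds_ratio_2x2(t),
        method="fisher_exact",
        exact=True,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at
    1, returned in the input order. NaN entries are excluded from the family
    and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    out[mask] = q
    return out


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when nx*ny <= 400 and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    The effect is the difference of group medians (median(x) - median(y)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size * y.size <= 400) and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        effect=float(np.median(x) - np.median(y)),
        method="mann_whitney_u",
        exact=exact,
    )


def wilcoxon_signed_rank(before, after) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on after - before.

    Zero differences are dropped. Exact p by enumerating sign assignments
    when n <= 25 with no tied |differences|; midranks + normal approximation
    with continuity correction otherwise. If every difference is zero the
    result is degenerate with p = 1. The effect is the median paired
    difference (including zero pairs).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("paired samples must have equal length")
    if b.size < 2:
        raise ValueError("need at least 2 pairs")
    d_all = a - b
    d = d_all[d_all != 0]
    effect = float(np.median(d_all))
    if d.size == 0:
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            effect=effect,
            method="wilcoxon_signed_rank",
            exact=True,
            degenerate=True,
        )
    absd = np.abs(d)
    has_ties = np.unique(absd).size < absd.size
    exact = (d.size <= 25) and not has_ties
    res = sps.wilcoxon(
        d,
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        effect=effect,
        method="wilcoxon_signed_rank",
        exact=exact,
    )


def quartiles(values) -> tuple[float, float]:
    """First and third quartiles, linear interpolation convention."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("need at least one finite value")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    return float(q1), float(q3)


def extreme_outlier_mask(values) -> np.ndarray:
    """Mask of values strictly beyond 3*IQR outside the quartile fences.

    Fewer than 4 finite values yields an all-false mask (the fences are not
    estimable robustly); NaN entries are never flagged. "More than" 3*IQR is
    strict, so a value exactly at a fence is retained.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    mask = np.zeros(v.shape, dtype=bool)
    if finite.sum() < 4:
        return mask
    q1, q3 = quartiles(v[finite])
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    mask[finite] = (v[finite] < lo) | (v[finite] > hi)
    return mask
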