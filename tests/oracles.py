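"""Independent brute-force oracles for the statistical primitives.

These deliberately avoid scipy/statsmodels: probabilities come from
``math.comb`` enumeration and the BH formula is applied definitionally, so
they provide an implementation-independent check of the package's tests.
"""

from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = comb(n, c1)

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / total

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # relative slack for float ties, matching the usual convention
    return min(
        1.0,
        sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7)),
    )


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Definitional BH step-up: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        i = rank_pos + 1
        q[idx] = min(
            1.0,
            min(
                m * p[order[j]] / (j + 1)
                for j in range(rank_pos, m)
            ),
        )
    return q


def mann_whitney_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p over all arrangements (tie-free)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for combo in combinations(range(n + m), n):
        rank_sum = sum(i + 1 for i in combo)
        us.append(rank_sum - n * (n + 1) / 2)
    us = np.array(us)
    total = us.size
    p = 2 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total
    return u_obs, min(1.0, p)


def wilcoxon_exact_oracle(diffs) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in range(2**n):
        w = sum(ranks[i] for i in range(n) if (signs >> i) & 1)
        ws.append(w)
    ws = np.array(ws, dtype=float)
    total = ws.size
    p = 2 * min((ws <= w_obs).sum(), (ws >= w_obs).sum()) / total
    return w_obs, min(1.0, p)


def quantile_oracle(values, q: float) -> float:
    """Linear-interpolation quantile: index = q*(n-1) on the sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    h = q * (v.size - 1)
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))
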