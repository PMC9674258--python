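"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles (exact rational
hypergeometric enumeration, exhaustive permutation of labelings) and shares
no code path with the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hypergeom_pmf_exact(k: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(top-left cell = k) for fixed margins, as an exact rational."""
    n = r1 + r2
    if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
        return Fraction(0)
    return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))


def fisher_exact_oracle(a: int, b: int, c: int, d: int, sided: str = "two"
                        ) -> float:
    """Fisher p by exhaustive enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    p_obs = hypergeom_pmf_exact(a, r1, r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf_exact(k, r1, r2, c1)
        if sided == "two":
            if pk <= p_obs:
                total += pk
        elif sided in ("greater", "one"):
            if k >= a:
                total += pk
        else:
            raise ValueError(sided)
    return float(total)


def mannwhitney_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Tie-free data assumed.  p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    x, y = list(map(float, x)), list(map(float, y))
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for xi in grp for yj in rest if xi > yj))
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def ks_statistic_oracle(x, y) -> float:
    """Two-sample KS statistic as the max gap between empirical CDFs."""
    x, y = np.sort(np.asarray(x, float)), np.sort(np.asarray(y, float))
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / len(x)
    cdf_y = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def ks_exact_oracle(x, y) -> float:
    """Exact two-sample KS p by enumerating all label assignments."""
    x, y = list(map(float, x)), list(map(float, y))
    pooled = x + y
    d_obs = ks_statistic_oracle(x, y)
    n1 = len(x)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if ks_statistic_oracle(grp, rest) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def poisson_tail_oracle(observed: int, lam: float, terms: int = 2000) -> float:
    """P(X >= observed) by direct series summation of the Poisson pmf."""
    if observed == 0:
        return 1.0
    from math import exp, factorial

    acc = 0.0
    for k in range(observed):
        acc += lam ** k * exp(-lam) / factorial(k)
    return 1.0 - acc
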