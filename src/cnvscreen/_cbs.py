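"""Numerical kernels for circular binary segmentation.

The split statistic for an arc ``[i, j)`` of a circularized series x of
length n (vs. its complement) is the standardized mean difference

    T(i, j) = |C_j - C_i| / ( s * sqrt( k (n - k) / n ) ),   k = j - i,

where ``C`` is the cumulative sum of the mean-centered series (C_0 = C_n =
0, so wrapped arcs are covered by indexing modulo n) and ``s`` a scale
estimate of the series.  ``s`` is invariant under permutations of the
values, so all kernels work with the *unstandardized* statistic
``|C_j - C_i| / sqrt(k (n - k) / n)``: the permutation test and the argmax
are unchanged.

Exact maximization scans every arc with ``k <= n // 2`` (each unordered
change-point pair is covered once, wrapped arcs included).  A range bound
``max_T(k) <= (max C - min C) / sqrt(k (n-k)/n)``, monotonically decreasing
in k up to n/2, lets the scan stop early once no remaining width can beat
the current best.

For long series the permutation null is evaluated on a geometric ladder of
arc widths (every width up to 16, then factors of ~1.25) instead of all
O(n^2) arcs; the observed statistic entering that test is maximized over
the same ladder, so the comparison is a valid permutation test of the
restricted-family maximum.  Split *locations* always come from the exact
scan.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LADDER_BASE = 16
LADDER_FACTOR = 1.25


def ladder_widths(n: int, kmin: int = 1, kmax: int | None = None) -> np.ndarray:
    """Geometric ladder of arc widths for permutation scans."""
    if kmax is None:
        kmax = n // 2
    ks: list[int] = []
    k = max(1, kmin)
    while k <= min(LADDER_BASE, kmax):
        ks.append(k)
        k += 1
    fk = float(max(ks[-1] if ks else kmin, 1))
    while True:
        fk *= LADDER_FACTOR
        k = int(fk)
        if k > kmax:
            break
        if not ks or k > ks[-1]:
            ks.append(k)
    if not ks:
        ks = [max(1, min(kmin, kmax))]
    return np.asarray(ks, dtype=np.int64)


@njit(cache=True)
def centered_cumsum(x):
    n = x.size
    m = 0.0
    for t in range(n):
        m += x[t]
    m /= n
    C = np.empty(n + 1)
    C[0] = 0.0
    for t in range(n):
        C[t + 1] = C[t] + x[t] - m
    return C


@njit(cache=True)
def max_arc_stat(C, n, kmin, kmax):
    """Exact max of the arc statistic; returns (stat, i, j).

    j may exceed n, meaning the arc wraps: change points are then
    (j - n, i) in linear order.  Ties resolve to the smallest width, then
    the smallest start — fully deterministic.
    """
    best = -1.0
    bi = 0
    bj = 0
    cmax = C[0]
    cmin = C[0]
    for t in range(1, n + 1):
        if C[t] > cmax:
            cmax = C[t]
        if C[t] < cmin:
            cmin = C[t]
    R = cmax - cmin
    for k in range(kmin, kmax + 1):
        denom = math.sqrt(k * (n - k) / n)
        if R / denom <= best:
            break  # bound decreases with k; nothing further can win
        for i in range(n):
            j = i + k
            cj = C[j] if j <= n else C[j - n]
            d = abs(cj - C[i])
            s = d / denom
            if s > best:
                best = s
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def ladder_max_stat(C, n, widths):
    """Max of the arc statistic over the width ladder (all positions)."""
    best = -1.0
    for w in range(widths.size):
        k = widths[w]
        if k < 1 or k > n - 1:
            continue
        denom = math.sqrt(k * (n - k) / n)
        for i in range(n):
            j = i + k
            cj = C[j] if j <= n else C[j - n]
            s = abs(cj - C[i]) / denom
            if s > best:
                best = s
    return best


@njit(cache=True)
def _exceeds_exact(C, n, obs, kmin, kmax):
    cmax = C[0]
    cmin = C[0]
    for t in range(1, n + 1):
        if C[t] > cmax:
            cmax = C[t]
        if C[t] < cmin:
            cmin = C[t]
    R = cmax - cmin
    for k in range(kmin, kmax + 1):
        denom = math.sqrt(k * (n - k) / n)
        if R / denom < obs:
            break
        # ties count as exceedances (the observed labelling is itself a
        # permutation); the tolerance absorbs round-trip rounding of obs*denom
        thr = obs * denom * (1.0 - 1e-9)
        for i in range(n):
            j = i + k
            cj = C[j] if j <= n else C[j - n]
            if abs(cj - C[i]) >= thr:
                return True
    return False


@njit(cache=True)
def _exceeds_ladder(C, n, obs, widths):
    cmax = C[0]
    cmin = C[0]
    for t in range(1, n + 1):
        if C[t] > cmax:
            cmax = C[t]
        if C[t] < cmin:
            cmin = C[t]
    R = cmax - cmin
    for w in range(widths.size):
        k = widths[w]
        if k < 1 or k > n - 1:
            continue
        denom = math.sqrt(k * (n - k) / n)
        if R / denom < obs:
            continue
        thr = obs * denom * (1.0 - 1e-9)
        for i in range(n):
            j = i + k
            cj = C[j] if j <= n else C[j - n]
            if abs(cj - C[i]) >= thr:
                return True
    return False


@njit(cache=True)
def perm_test(x, obs, widths, n_perm, alpha, min_accept, seed, exact, kmin, kmax):
    """Permutation p-value decision for a candidate split.

    Returns (exceed_count, permutations_done, significant).  Sequential
    early stopping: the loop rejects the split as soon as the exceedance
    count guarantees p > alpha, and accepts once ``min_accept``
    permutations have produced no exceedance.
    """
    n = x.size
    np.random.seed(seed)
    y = x.copy()
    reject_count = int(alpha * n_perm)
    count = 0
    for b in range(n_perm):
        for t in range(n - 1, 0, -1):  # Fisher-Yates
            r = np.random.randint(0, t + 1)
            tmp = y[t]
            y[t] = y[r]
            y[r] = tmp
        C = centered_cumsum(y)
        if exact:
            hit = _exceeds_exact(C, n, obs, kmin, kmax)
        else:
            hit = _exceeds_ladder(C, n, obs, widths)
        if hit:
            count += 1
            if count > reject_count:
                return count, b + 1, False
        elif count == 0 and b + 1 >= min_accept:
            return 0, b + 1, True
    return count, n_perm, count / n_perm < alpha
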