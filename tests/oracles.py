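"""Independent brute-force oracles used by the test suite.

Everything here is written against the documented algorithm contracts, not
against the package internals: statistics are recomputed from scratch in
pure Python so that the production implementations are checked against an
independent path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# --- circular binary segmentation ------------------------------------------

CHECKPOINTS = (500, 1000, 2000, 5000)


def arc_stat(x: list[float], i: int, j: int) -> float:
    """Mean-shift statistic of arc (i, j] computed naively from slices."""
    n = len(x)
    inside = x[i:j]
    outside = x[:i] + x[j:]
    k = len(inside)
    d = sum(inside) / k - sum(outside) / (n - k)
    return abs(d) * math.sqrt(k * (n - k) / n)


def best_arc_bruteforce(x: list[float], min_width: int):
    """Exhaustive max over every arc; ties -> smaller width, then smaller i."""
    n = len(x)
    best, bi, bj = -1.0, -1, -1
    for k in range(min_width, n - min_width + 1):
        for i in range(0, n - k + 1):
            t = arc_stat(x, i, i + k)
            if t > best:
                best, bi, bj = t, i, i + k
    return best, bi, bj


def split_decision_bruteforce(x, alpha, nperm, min_width, rng):
    """Sequential permutation decision, replayed with a naive stat."""
    obs, i, j = best_arc_bruteforce(list(x), min_width)
    if obs <= 0 or i < 0:
        return False, i, j
    hard_reject = math.ceil(alpha * (1 + nperm))
    thresh = obs - 1e-9 * max(1.0, abs(obs))  # tie tolerance
    e = 0
    for m in range(1, nperm + 1):
        perm = rng.permutation(len(x))
        stat, _, _ = best_arc_bruteforce([x[p] for p in perm], min_width)
        if stat >= thresh:
            e += 1
        if e >= hard_reject:
            return False, i, j
        if e >= 5 and (1 + e) >= alpha * (1 + m):
            return False, i, j
        if m in CHECKPOINTS and m < nperm:
            if (1 + e) * 5 < alpha * (1 + m):
                return True, i, j
            if 2 * (1 + e) >= alpha * (1 + m):
                return False, i, j
    return (1 + e) < alpha * (1 + nperm), i, j


def cbs_bruteforce(x, chrom_rank, alpha, nperm, min_width, seed):
    """Full recursion over every circular split with the same seeded
    permutation streams as the production engine's contract."""

    def recurse(values, offset):
        n = len(values)
        if n < 2 * min_width:
            return [(offset, offset + n)]
        rng = np.random.default_rng([seed, chrom_rank, offset, n])
        significant, i, j = split_decision_bruteforce(
            values, alpha, nperm, min_width, rng
        )
        if not significant:
            return [(offset, offset + n)]
        spans = []
        for lo, hi in ((0, i), (i, j), (j, n)):
            if hi > lo:
                spans.extend(recurse(values[lo:hi], offset + lo))
        return spans

    return recurse(list(x), 0)


def two_changepoint_lsq(x: np.ndarray):
    """Exhaustive least-squares fit of exactly two change-points (i < j)."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(a, b):
        if b == a:
            return 0.0
        return (s2[b] - s2[a]) - (s[b] - s[a]) ** 2 / (b - a)

    best, bi, bj = math.inf, -1, -1
    for i in range(1, n - 1):
        for j in range(i + 1, n):
            total = sse(0, i) + sse(i, j) + sse(j, n)
            if total < best:
                best, bi, bj = total, i, j
    return bi, bj


# --- rank-sum test ----------------------------------------------------------

def wilcoxon_exact_bruteforce(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration of label assignments."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    values = list(x) + list(y)
    ranks = {v: r for r, v in enumerate(sorted(values), start=1)}
    w_obs = sum(ranks[v] for v in x)
    ws = [
        sum(ranks[values[i]] for i in comb)
        for comb in itertools.combinations(range(len(values)), n1)
    ]
    n_le = sum(w <= w_obs for w in ws)
    n_ge = sum(w >= w_obs for w in ws)
    return min(1.0, 2 * min(n_le, n_ge) / len(ws))


# --- set cover ---------------------------------------------------------------

def minimum_set_cover_size(universe: set, subsets: list[set]) -> int | None:
    """Smallest number of subsets covering every coverable element."""
    coverable = set().union(*subsets) & universe if subsets else set()
    for size in range(0, len(subsets) + 1):
        for combo in itertools.combinations(range(len(subsets)), size):
            if set().union(*(subsets[i] for i in combo), set()) >= coverable:
                return size
    return None


# --- exact binomial interval -------------------------------------------------

def clopper_pearson_bruteforce(x: int, n: int, level: float = 0.95):
    """CI by direct inversion of binomial tail probabilities (bisection)."""
    from scipy.stats import binom

    a = (1 - level) / 2

    def bisect(f, lo, hi):
        for _ in range(60):
            mid = (lo + hi) / 2
            if f(mid):
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    lo = 0.0 if x == 0 else bisect(lambda p: binom.sf(x - 1, n, p) > a, 0.0, 1.0)
    hi = 1.0 if x == n else bisect(lambda p: binom.cdf(x, n, p) < a, 0.0, 1.0)
    return lo, hi
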