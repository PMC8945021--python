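"""Independent oracles used by the test suite.

Each oracle is deliberately naive — exact rational arithmetic, explicit urn
simulation, exhaustive enumeration — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def exact_hypergeom_pmf(x: int, n: int, N: int, M: int) -> Fraction:
    """C(n,x) C(M−n,N−x) / C(M,N) in exact big-integer arithmetic."""
    return Fraction(comb(n, x) * comb(M - n, N - x), comb(M, N))


def exact_hypergeom_upper_tail(x: int, n: int, N: int, M: int) -> Fraction:
    hi = min(n, N)
    return sum((exact_hypergeom_pmf(k, n, N, M) for k in range(x, hi + 1)), Fraction(0))


def wallenius_urn_counts(M: int, n: int, N: int, w: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate the biased urn: N sequential draws without replacement,
    each draw taking an in-category ball with probability w·r1/(w·r1+r2)
    where r1, r2 are the remaining in/out counts. Returns the in-category
    draw count per replicate."""
    r1 = np.full(size, n, dtype=np.int64)
    r2 = np.full(size, M - n, dtype=np.int64)
    x = np.zeros(size, dtype=np.int64)
    for _ in range(N):
        denom = w * r1 + r2
        p1 = np.where(denom > 0, w * r1 / np.maximum(denom, 1e-300), 0.0)
        take = rng.random(size) < p1
        x += take
        r1 -= take
        r2 -= ~take
    return x


def enumerate_frequent_itemsets(transactions: list[frozenset], min_count: int) -> dict[frozenset, int]:
    """All itemsets with support >= min_count, by exhaustive enumeration."""
    items = sorted(set().union(*transactions)) if transactions else []
    out: dict[frozenset, int] = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            iset = frozenset(combo)
            sup = sum(1 for t in transactions if iset <= t)
            if sup >= min_count:
                out[iset] = sup
    return out


def enumerate_closed(freq: dict[frozenset, int]) -> set[frozenset]:
    return {
        i for i, s in freq.items()
        if not any(i < j and sj == s for j, sj in freq.items())
    }


def enumerate_maximal(freq: dict[frozenset, int]) -> set[frozenset]:
    return {i for i in freq if not any(i < j for j in freq)}


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Closed-form BH step-up: q(i) = min_{j>=i} min(1, p(j)·m/j) on the
    sorted p-values, mapped back to input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, pvalues[i] * m / rank))
        adj_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out
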