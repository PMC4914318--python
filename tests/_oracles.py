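"""Independent brute-force oracles used only by the tests.

Each oracle is a from-first-principles implementation of the statistic it
checks, deliberately sharing no code with the package: rank-split
enumeration for the exact Wilcoxon null, integer-combinatorics
hypergeometric tails for the one-sided Fisher test, the literal step-up
recipe for Benjamini-Hochberg, and an O(n^3) agglomeration loop for UPGMA.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exact_wilcoxon_two_sided(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating every rank assignment.

    Requires tie-free pooled data.  p = P(|U - mu| >= |u_obs - mu|) under
    the permutation null, which for the symmetric U null equals the
    doubled smaller tail.
    """
    x = list(x)
    y = list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n + m, "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - n * (n + 1) / 2
    mu = n * m / 2
    hits = 0
    total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def fisher_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the hypergeometric with the table's margins, by
    exact integer combinatorics."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n_total, row1)
    lo = max(0, row1 - (n_total - col1))
    hi = min(row1, col1)
    num = sum(
        math.comb(col1, x) * math.comb(n_total - col1, row1 - x)
        for x in range(max(a, lo), hi + 1)
    )
    return num / denom


def naive_bh(pvals) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def naive_upgma(dist: np.ndarray):
    """O(n^3) UPGMA: average of all leaf-pair distances between clusters.

    Merges the closest pair each round, breaking distance ties by the
    lexicographically smallest cluster-index pair.  Returns the merge
    history as ``[(leaf_set_a, leaf_set_b, height), ...]`` in merge order.
    """
    n = dist.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges = []
    d = {
        (i, j): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        pairs = [(min(i, j), max(i, j)) for i, j in itertools.combinations(ids, 2)]
        best = min(pairs, key=lambda k: (d[k], k))
        i, j = best
        height = d[best]
        merges.append((clusters[i], clusters[j], height))
        merged = clusters[i] | clusters[j]
        ni, nj = len(clusters[i]), len(clusters[j])
        del clusters[i], clusters[j]
        for k in clusters:
            a = (min(i, k), max(i, k))
            b = (min(j, k), max(j, k))
            d[(min(next_id, k), max(next_id, k))] = (
                ni * d[a] + nj * d[b]
            ) / (ni + nj)
        clusters[next_id] = merged
        next_id += 1
    return merges


def kruskal_h(groups) -> float:
    """Kruskal-Wallis H from the textbook midrank formula with tie correction."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        r = ranks[start : start + k]
        h += r.sum() ** 2 / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie
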