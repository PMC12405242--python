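"""Independent brute-force oracles used by the test suite only."""

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def ranksum_p_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p by literally enumerating every assignment."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    n = len(pooled)
    lo = hi = total = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def bh_stepup_bruteforce(pvalues) -> np.ndarray:
    """Literal step-up definition: adj_i = min_{j: p_j >= p_i} (p_j * m / rank_j)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos_i, i in enumerate(order):
        best = 1.0
        for pos_j in range(pos_i, m):
            j = order[pos_j]
            best = min(best, p[j] * m / (pos_j + 1))
        adj[i] = best
    return adj


def naive_ward_merge_partitions(x) -> list[frozenset]:
    """O(n^3) Ward clustering; returns the partition after every merge.

    Merge criterion: minimize the ESS increase
    |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2, evaluated freshly over
    all cluster pairs at every step.
    """
    x = np.asarray(x, dtype=float)
    clusters = [[i] for i in range(x.shape[0])]
    partitions = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            ca = x[clusters[a]].mean(axis=0)
            cb = x[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            delta = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
            if best is None or delta < best[0]:
                best = (delta, a, b)
        _, a, b = best
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        partitions.append(frozenset(frozenset(c) for c in clusters))
    return partitions


def hypergeom_tail_enumeration(k, big_n, big_k, n_draw) -> float:
    """P(X >= k) for a hypergeometric by direct summation of binomials."""
    total = comb(big_n, n_draw)
    acc = 0
    for i in range(k, min(big_k, n_draw) + 1):
        if n_draw - i <= big_n - big_k:
            acc += comb(big_k, i) * comb(big_n - big_k, n_draw - i)
    return acc / total


def scipy_linkage_partitions(z, n) -> list[frozenset]:
    """Partition sequence implied by a scipy linkage matrix."""
    clusters = {i: frozenset([i]) for i in range(n)}
    partitions = []
    for step, (a, b, _, _) in enumerate(z):
        merged = clusters.pop(int(a)) | clusters.pop(int(b))
        clusters[n + step] = merged
        partitions.append(frozenset(clusters.values()))
    return partitions
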