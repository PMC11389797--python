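"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: brute-force
enumeration over rank arrangements and subset pairs, and closed-form
expectations, at sizes small enough to be exact.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def enum_mw_two_sided_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank arrangements.

    Counts arrangements whose U is at least as far from the null center
    n1*n2/2 as the observed one (tie-free data assumed).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1, n = a.size, pooled.size
    ranks = stats.rankdata(pooled)
    center = n1 * (n - n1) / 2.0

    def u_of(idx) -> float:
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    deviations = np.array(
        [abs(u_of(c) - center) for c in combinations(range(n), n1)]
    )
    return float(np.mean(deviations >= abs(u_obs - center) - 1e-9))


def enum_overlap_null(
    agree: np.ndarray, size_a: int, size_b: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the direction-consistent overlap.

    Enumerates every pair of subsets (sizes ``size_a``, ``size_b``) of a
    universe of ``len(agree)`` genes; ``agree[g]`` says whether gene g's
    observed signs agree between the two cohorts.  Returns (values, probs).
    """
    G = agree.size
    overlaps = []
    subsets_b = list(combinations(range(G), size_b))
    for sub_a in combinations(range(G), size_a):
        in_a = np.zeros(G, dtype=bool)
        in_a[list(sub_a)] = True
        for sub_b in subsets_b:
            overlaps.append(
                sum(1 for g in sub_b if in_a[g] and agree[g])
            )
    values, counts = np.unique(np.asarray(overlaps), return_counts=True)
    return values, counts / counts.sum()


def average_linkage_merge_order(dist: np.ndarray) -> list[tuple]:
    """Hand-rolled average-linkage agglomeration over a small square
    distance matrix; returns the merge sequence as frozensets of leaves."""
    clusters = {i: frozenset([i]) for i in range(dist.shape[0])}
    merges = []
    while len(clusters) > 1:
        keys = list(clusters)
        best = None
        for i, j in combinations(keys, 2):
            d = np.mean(
                [dist[a, b] for a in clusters[i] for b in clusters[j]]
            )
            if best is None or d < best[0]:
                best = (d, i, j)
        _, i, j = best
        merged = clusters.pop(i) | clusters.pop(j)
        merges.append(merged)
        clusters[max(keys) + 1] = merged
    return merges
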