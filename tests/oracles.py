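"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_pr_curve(scores, positives, negatives, direction="most_negative_first"):
    """PR points and trapezoid AUC by explicit threshold enumeration."""
    items = sorted(set(positives) | set(negatives))

    def goodness(it):
        v = scores.get(it, 0.0)
        if direction == "most_negative_first":
            return -v
        if direction == "largest_magnitude_first":
            return abs(v)
        return v

    values = sorted({goodness(it) for it in items}, reverse=True)
    points = []
    for thr in values:
        called = [it for it in items if goodness(it) >= thr]
        tp = sum(1 for it in called if it in positives)
        fp = len(called) - tp
        points.append((tp / len(positives), tp / (tp + fp)))
    recalls = [0.0] + [r for r, _ in points]
    precisions = [points[0][1]] + [p for _, p in points]
    auc = 0.0
    for i in range(1, len(recalls)):
        auc += (recalls[i] - recalls[i - 1]) * (precisions[i] + precisions[i - 1]) / 2
    return points, auc


def brute_overlap_counts(ranked_pairs, validated, ks):
    return [sum(1 for p in ranked_pairs[:k] if p in validated) for k in ks]


def brute_rand_index(a, b):
    n = len(a)
    agree = 0
    for i, j in combinations(range(n), 2):
        agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / (n * (n - 1) / 2)


def brute_bh(pvalues):
    """Step-up BH by direct definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adjusted[i] = val
        prev = val
    return adjusted


def brute_average_linkage(dist, k):
    """O(N^3) agglomerative average linkage on a precomputed distance matrix.

    Returns cluster labels (arbitrary numbering) after cutting at k clusters.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters):
        labels[list(members)] = lab
    return labels


def brute_signed_rank_p(diffs, alternative="two-sided"):
    """Exact Wilcoxon signed-rank p-value by enumerating all sign patterns."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # midranks for ties
    absd = np.abs(d)
    for v in set(absd):
        idx = [i for i in range(n) if absd[i] == v]
        ranks[idx] = np.mean(ranks[idx])
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    stats = []
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        stats.append(w)
    stats = np.array(stats)
    if alternative == "greater":
        return float((stats >= w_obs).mean())
    if alternative == "less":
        return float((stats <= w_obs).mean())
    p = 2 * min((stats >= w_obs).mean(), (stats <= w_obs).mean())
    return float(min(1.0, p))
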