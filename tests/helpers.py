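"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (normal equations, O(n^3) loops,
exhaustive scans) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def ols_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Normal-equations solution (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def correlation_distance_oracle(X: np.ndarray) -> np.ndarray:
    """Two-pass Pearson correlation distance, elementwise."""
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            denom = np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
            D[i, j] = 1.0 - (xi @ xj) / denom
    return D


def complete_linkage_oracle(D: np.ndarray):
    """Naive O(n^3) agglomerative complete linkage.

    Returns (heights, partitions) where heights is the sorted list of merge
    heights and partitions[k] is the frozenset-of-frozensets partition into
    k clusters obtained by undoing the last merges.
    """
    n = D.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    heights: list[float] = []
    snapshots = {len(clusters): frozenset(frozenset(c) for c in clusters)}
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        snapshots[len(clusters)] = frozenset(frozenset(c) for c in clusters)
    return sorted(heights), snapshots


def fdr_threshold_oracle(p_values: np.ndarray, target: float):
    """Exhaustive scan over observed p-values; returns (p_star, S) with the
    largest S whose N*p/S <= target, or (None, 0)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    best_s, best_p = 0, None
    for cand in np.unique(p):
        s = int((p <= cand).sum())
        if n * cand / s <= target and s > best_s:
            best_s, best_p = s, float(cand)
    return best_p, best_s


def comembership_agreement(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Fraction of item pairs on which two partitions agree about
    co-membership (Rand index)."""
    truth = np.asarray(truth)
    estimate = np.asarray(estimate)
    n = truth.shape[0]
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (truth[i] == truth[j]) == (estimate[i] == estimate[j]):
                agree += 1
    return agree / total


def adjusted_rand(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Adjusted Rand index from the pair-count contingency table."""
    truth = np.asarray(truth)
    estimate = np.asarray(estimate)
    t_vals, t_inv = np.unique(truth, return_inverse=True)
    e_vals, e_inv = np.unique(estimate, return_inverse=True)
    table = np.zeros((t_vals.size, e_vals.size), dtype=int)
    for a, b in zip(t_inv, e_inv):
        table[a, b] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    n = truth.shape[0]
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
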