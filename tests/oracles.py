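"""Independent brute-force oracles used to validate the implementation.

These deliberately use naive enumeration (python loops, O(n^3) clustering)
and never call the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_cooccurrence(levels, shift, n_gray, symmetric=True):
    """Pair enumeration with explicit loops."""
    levels = np.asarray(levels)
    h, w = levels.shape
    dr, dc = shift
    counts = np.zeros((n_gray, n_gray))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[levels[r, c], levels[r2, c2]] += 1
                if symmetric:
                    counts[levels[r2, c2], levels[r, c]] += 1
    return counts / counts.sum()


def brute_statistics(P):
    """Direct scalar-loop evaluation of the seven GLCM statistics."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    mean = sum(i * P[i, j] for i in range(n) for j in range(n))
    out = {
        "mean": mean,
        "variance": sum((i - mean) ** 2 * P[i, j] for i in range(n) for j in range(n)),
        "contrast": sum((i - j) ** 2 * P[i, j] for i in range(n) for j in range(n)),
        "dissimilarity": sum(abs(i - j) * P[i, j] for i in range(n) for j in range(n)),
        "homogeneity": sum(P[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)),
        "second_moment": sum(P[i, j] ** 2 for i in range(n) for j in range(n)),
        "entropy": -sum(
            P[i, j] * math.log(P[i, j]) for i in range(n) for j in range(n) if P[i, j] > 0
        ),
    }
    return out


def brute_window_cooccurrence(levels, pr, pc, window, shifts, n_gray, symmetric=True):
    """Pooled pair enumeration restricted to one window (both endpoints
    inside the window centered at (pr, pc))."""
    half = window // 2
    counts = np.zeros((n_gray, n_gray))
    for dr, dc in shifts:
        for r in range(pr - half, pr + half + 1):
            for c in range(pc - half, pc + half + 1):
                r2, c2 = r + dr, c + dc
                if pr - half <= r2 <= pr + half and pc - half <= c2 <= pc + half:
                    counts[levels[r, c], levels[r2, c2]] += 1
                    if symmetric:
                        counts[levels[r2, c2], levels[r, c]] += 1
    return counts / counts.sum()


def naive_upgma_cophenetic(dist):
    """O(n^3) UPGMA; returns the cophenetic distance matrix.

    Clusters are merged at the average of all cross-pair distances from
    the original matrix, recomputed from scratch at every step.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
    return coph
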