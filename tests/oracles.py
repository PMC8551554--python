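"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (series expansions, exhaustive
enumeration, hand-rolled Floyd-Warshall) and shares no code with the
package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bessel_ratio_series(x: float, terms: int = 60) -> float:
    """I1(x)/I0(x) via the ascending power series of each Bessel function."""
    i0 = sum((x / 2) ** (2 * m) / math.factorial(m) ** 2 for m in range(terms))
    i1 = sum((x / 2) ** (2 * m + 1) / (math.factorial(m) * math.factorial(m + 1))
             for m in range(terms))
    return i1 / i0


def brute_shortest_paths(w: np.ndarray) -> np.ndarray:
    """Floyd-Warshall on distances 1/w; plain triple loop."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_char_path_length(w: np.ndarray) -> float:
    d = brute_shortest_paths(w)
    n = w.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def brute_global_efficiency(w: np.ndarray) -> float:
    d = brute_shortest_paths(w)
    n = w.shape[0]
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def brute_onnela_clustering(w: np.ndarray) -> np.ndarray:
    """Per-node weighted clustering by exhaustive triple enumeration."""
    n = w.shape[0]
    wmax = w.max()
    c = np.zeros(n)
    if wmax == 0:
        return c
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.permutations(range(n), 2):
            if j == i or h == i:
                continue
            if w[i, j] > 0 and w[j, h] > 0 and w[i, h] > 0:
                total += ((w[i, j] / wmax) * (w[j, h] / wmax)
                          * (w[i, h] / wmax)) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def brute_local_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        eloc[i] = brute_global_efficiency(sub)
    return eloc


def brute_top_k_edges(w: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Top-k off-diagonal edges by full sort (ties: lexicographic)."""
    n = w.shape[0]
    edges = sorted(((i, j) for i in range(n) for j in range(i + 1, n)),
                   key=lambda e: (-w[e], e[0], e[1]))
    return set(edges[:k])


def random_weighted_graph(rng: np.random.Generator, n: int,
                          p_edge: float = 0.7, binary: bool = False) -> np.ndarray:
    """Random symmetric weighted adjacency with zero diagonal."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = 1.0 if binary else rng.uniform(0.1, 1.0)
    return w
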