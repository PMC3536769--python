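"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible from first principles
(explicit loops, closed forms) and never calls into the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def pearson(x, y) -> float:
    """Pearson correlation by the textbook formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum()))


def triplet_value(wij: float, wik: float, rule: str) -> float:
    if rule == "arithmetic_mean":
        return (wij + wik) / 2.0
    if rule == "geometric_mean":
        return math.sqrt(wij * wik)
    if rule == "max":
        return max(wij, wik)
    return min(wij, wik)


def brute_global_clustering(w: np.ndarray, rule: str, weighted: bool = True) -> float:
    """Triplet-based clustering by explicit enumeration of all centered triplets."""
    n = w.shape[0]
    a = w > 0
    W = w if weighted else a.astype(float)
    total = 0.0
    closed = 0.0
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if j == i or k == i:
                    continue
                if a[i, j] and a[i, k]:
                    v = triplet_value(W[i, j], W[i, k], rule)
                    total += v
                    if a[j, k]:
                        closed += v
    return closed / total if total > 0 else 0.0


def brute_local_clustering(w: np.ndarray) -> float:
    """Watts–Strogatz average local clustering on the binary support."""
    n = w.shape[0]
    a = w > 0
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for j, l in combinations(nb, 2) if a[j, l])
        vals.append(links / (k * (k - 1) / 2.0))
    return float(np.mean(vals))


def brute_distances(w: np.ndarray, weighted: bool = True, alpha: float = 1.0) -> np.ndarray:
    """All-pairs shortest paths by Floyd–Warshall dynamic programming."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = (1.0 / w[i, j]) ** alpha if weighted else 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def brute_path_length(d: np.ndarray) -> tuple[float, float]:
    """Mean finite off-diagonal distance over unordered pairs + reachable fraction."""
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(i + 1, n)]
    finite = [v for v in vals if math.isfinite(v)]
    frac = len(finite) / len(vals)
    return (float(np.mean(finite)) if finite else float("nan")), frac


def pooled_t(x, y) -> tuple[float, float, float]:
    """(t, df, cohens_d) for the pooled two-sample t-test, textbook closed form."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    na, nb = len(x), len(y)
    df = na + nb - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    d = (x.mean() - y.mean()) / math.sqrt(sp2)
    return t, float(df), d


def random_symmetric(rng: np.random.Generator, n: int, density: float = 0.6,
                     binary: bool = False) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    u = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(u * mask, 1)
    w = w + w.T
    if binary:
        w = (w > 0).astype(float)
    return w
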