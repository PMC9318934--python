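"""Independent brute-force oracles for graph descriptors.

Everything here is deliberately naive and separate from the package's
implementations: Floyd-Warshall hop counts, exact-rational betweenness via
shortest-path counting, literal all-simple-path enumeration for tiny
graphs, and direct neighbour-pair triangle counting.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def floyd_warshall_sp(A: np.ndarray) -> np.ndarray:
    """All-pairs hop counts by triple-loop Floyd-Warshall."""
    n = A.shape[0]
    INF = float("inf")
    sp = np.full((n, n), INF)
    np.fill_diagonal(sp, 0.0)
    sp[A == 1] = 1.0
    for k in range(n):
        for i in range(n):
            via = sp[i, k] + sp[k, :]
            sp[i] = np.minimum(sp[i], via)
    return sp


def path_count_betweenness(A: np.ndarray) -> list[Fraction]:
    """Exact betweenness from shortest-path counts (rational arithmetic).

    sigma[s][t] shortest-path counts are built over increasing path length;
    btw_i = sum over pairs s < t (both != i, sp_si + sp_it = sp_st) of
    sigma_si * sigma_it / sigma_st.
    """
    n = A.shape[0]
    sp = floyd_warshall_sp(A)
    # sigma via DP on the shortest-path DAG, ordered by distance from s
    sigma = np.zeros((n, n), dtype=object)
    for s in range(n):
        sigma[s, s] = 1
        order = sorted(range(n), key=lambda v: sp[s, v])
        for v in order:
            if v == s or not np.isfinite(sp[s, v]):
                continue
            total = 0
            for u in range(n):
                if A[u, v] == 1 and sp[s, u] == sp[s, v] - 1:
                    total += sigma[s, u]
            sigma[s, v] = total
    btw = [Fraction(0) for _ in range(n)]
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(sp[s, t]) or sigma[s, t] == 0:
            continue
        for i in range(n):
            if i in (s, t):
                continue
            if np.isfinite(sp[s, i]) and np.isfinite(sp[i, t]) and \
                    sp[s, i] + sp[i, t] == sp[s, t]:
                btw[i] += Fraction(int(sigma[s, i]) * int(sigma[i, t]), int(sigma[s, t]))
    return btw


def enumerate_betweenness(A: np.ndarray) -> list[Fraction]:
    """Literal enumeration of every shortest path (tiny graphs only)."""
    n = A.shape[0]
    sp = floyd_warshall_sp(A)
    btw = [Fraction(0) for _ in range(n)]
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(sp[s, t]):
            continue
        L = int(sp[s, t])
        paths = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if len(path) - 1 > L:
                continue
            if v == t and len(path) - 1 == L:
                paths.append(path)
                continue
            for w in range(n):
                if A[v, w] == 1 and w not in path:
                    stack.append((w, path + [w]))
        for path in paths:
            for i in path[1:-1]:
                btw[i] += Fraction(1, len(paths))
    return btw


def triangle_clustering(A: np.ndarray) -> np.ndarray:
    """cc_i by direct enumeration of connected neighbour pairs."""
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j] == 1]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if A[a, b] == 1
        )
        out[i] = links / (k * (k - 1) / 2)
    return out
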