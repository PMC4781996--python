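"""Independent brute-force oracles for graph metrics.

Everything here works by exhaustive enumeration of simple paths / neighbor
pairs, deliberately sharing no code with the package implementation. Only
usable for small graphs (N <= ~8).
"""

from __future__ import annotations

import numpy as np


def _neighbors(adj: np.ndarray, i: int) -> list[int]:
    return [j for j in range(adj.shape[0]) if adj[i, j]]


def all_simple_paths(adj: np.ndarray, src: int, dst: int) -> list[tuple[int, ...]]:
    """All simple paths src -> dst by DFS."""
    out: list[tuple[int, ...]] = []
    stack = [(src, (src,))]
    while stack:
        node, path = stack.pop()
        if node == dst:
            out.append(path)
            continue
        for nb in _neighbors(adj, node):
            if nb not in path:
                stack.append((nb, path + (nb,)))
    return out


def brute_degree(adj: np.ndarray) -> list[int]:
    return [len(_neighbors(adj, i)) for i in range(adj.shape[0])]


def brute_clustering(adj: np.ndarray) -> tuple[list[float], float]:
    n = adj.shape[0]
    per = []
    for i in range(n):
        nbrs = _neighbors(adj, i)
        k = len(nbrs)
        if k < 2:
            per.append(0.0)
            continue
        e = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if adj[nbrs[a], nbrs[b]]
        )
        per.append(2.0 * e / (k * (k - 1)))
    return per, float(np.mean(per))


def brute_shortest(adj: np.ndarray) -> dict[tuple[int, int], tuple[int, int]]:
    """For each unordered reachable pair: (geodesic length, geodesic count)."""
    n = adj.shape[0]
    out = {}
    for j in range(n):
        for k in range(j + 1, n):
            paths = all_simple_paths(adj, j, k)
            if not paths:
                continue
            d = min(len(p) - 1 for p in paths)
            cnt = sum(1 for p in paths if len(p) - 1 == d)
            out[(j, k)] = (d, cnt)
    return out


def brute_path_length(adj: np.ndarray) -> tuple[list[float], float, int]:
    """Per-node mean distance over reachable partners, global mean, unreachable pairs."""
    n = adj.shape[0]
    sp = brute_shortest(adj)
    dists: list[list[int]] = [[] for _ in range(n)]
    for (j, k), (d, _) in sp.items():
        dists[j].append(d)
        dists[k].append(d)
    per = [float(np.mean(d)) if d else float("nan") for d in dists]
    finite = [x for x in per if not np.isnan(x)]
    total_pairs = n * (n - 1) // 2
    return per, float(np.mean(finite)), total_pairs - len(sp)


def brute_betweenness(adj: np.ndarray) -> list[float]:
    """BC_i: fractional geodesic counting over unordered pairs, endpoints excluded."""
    n = adj.shape[0]
    bc = [0.0] * n
    for j in range(n):
        for k in range(j + 1, n):
            paths = all_simple_paths(adj, j, k)
            if not paths:
                continue
            d = min(len(p) - 1 for p in paths)
            geos = [p for p in paths if len(p) - 1 == d]
            for i in range(n):
                if i in (j, k):
                    continue
                through = sum(1 for p in geos if i in p[1:-1])
                bc[i] += through / len(geos)
    return bc
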