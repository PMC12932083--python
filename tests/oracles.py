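"""Brute-force reference implementations used only by the test suite.

Everything here is deliberately naive — enumeration over pairs,
triangles and explicit path expansion — and shares no code with the
package's metric implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_by_enumeration(adj: np.ndarray) -> np.ndarray:
    """Node clustering from explicit neighbour-pair counting."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def global_efficiency_by_pairs(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_by_pairs(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(global_efficiency_by_pairs(sub))
    return float(np.mean(vals))


def nodal_efficiency_by_pairs(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j != i and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
    return out / (n - 1)


def betweenness_by_path_enumeration(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via explicit shortest-path expansion."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]) or d[s, t] == 0:
            continue
        paths = _all_shortest_paths(adj, d, s, t)
        count = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / count
    return bc


def _all_shortest_paths(adj, d, s, t):
    target_len = int(d[s, t])
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        if len(path) - 1 >= target_len:
            continue
        for nxt in range(adj.shape[0]):
            if adj[node, nxt] and nxt not in path:
                # only extend along a shortest route
                if (len(path) - 1) + 1 + d[nxt, t] == target_len:
                    stack.append((nxt, path + [nxt]))
    return paths
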