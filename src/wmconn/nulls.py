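"""Degree-preserving null networks by Maslov-Sneppen double-edge swaps.

Each attempt draws two edges (a,b) and (c,d) and a random orientation
and proposes rewiring them to (a,d), (b,c); the attempt is rejected when
it would create a self-loop or a duplicate edge.  The degree sequence is
therefore preserved exactly.  Connectedness is not enforced.  The number
of *attempted* swaps is fixed (swaps-per-edge times edge count) so the
amount of randomization is comparable across graphs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .connectome import BinaryGraph

__all__ = ["rewire_null"]


@njit(cache=True)
def _swap_loop(adj, eu, ev, n_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    m = eu.shape[0]
    for _ in range(n_attempts):
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = eu[e1], ev[e1]
        c, d = eu[e2], ev[e2]
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[b, c]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[b, c] = True
        adj[c, b] = True
        ev[e1] = d
        eu[e2] = b
        ev[e2] = c


def rewire_null(
    g: BinaryGraph, n_swaps_per_edge: int = 10, seed: int | None = None
) -> BinaryGraph:
    """Rewire a graph into a degree-matched random null.

    Performs ``n_swaps_per_edge * n_edges`` swap attempts; graphs with
    no legal swap (e.g. complete graphs) come back unchanged.
    """
    if g.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    adj = g.adjacency.copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    eu = iu.astype(np.int64)
    ev = ju.astype(np.int64)
    n_attempts = int(n_swaps_per_edge) * eu.shape[0]
    rng_seed = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    _swap_loop(adj, eu, ev, n_attempts, int(rng_seed))
    return BinaryGraph(adj, sparsity=g.sparsity)
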