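"""Node time-series extraction, Fisher-z connectivity, sparsity binarization.

Each subject's connectome is the N x N matrix of Fisher-z transformed
Pearson correlations between parcel-averaged BOLD series.  Graph
analysis operates on binary adjacency matrices obtained by keeping the
strongest edges at a target sparsity (edge count / maximum possible
edges), swept over a grid; edge sets along the grid are nested because
the same deterministic edge ranking is truncated at each level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parcellation import Parcellation
from .preprocess import CensorMask

__all__ = [
    "NodeTimeSeries",
    "ConnMatrix",
    "BinaryGraph",
    "node_timeseries",
    "correlation_matrix",
    "binarize_at_sparsity",
    "edge_ranking",
    "n_edges_at_sparsity",
]

_Z_CLIP = 1.0 - 1e-15


@dataclass(frozen=True)
class NodeTimeSeries:
    """Parcel-averaged BOLD series: n_nodes x n_kept_frames."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("node time series must be 2-D (nodes x frames)")
        if not np.isfinite(values).all():
            raise ValueError("node time series contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnMatrix:
    """Symmetric Fisher-z connectivity matrix with a zero diagonal."""

    z: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(z).all():
            raise ValueError("connectivity matrix contains non-finite values")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(np.diag(z)).max() > 0:
            raise ValueError("connectivity matrix diagonal must be zero")
        object.__setattr__(self, "z", z)

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected binary adjacency at a fixed sparsity; no self-loops."""

    adjacency: np.ndarray
    sparsity: float = float("nan")

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if (adj != adj.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diag(adj).any():
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)


def node_timeseries(
    voxel_series: np.ndarray,
    parcellation: Parcellation,
    censor: CensorMask | None = None,
    subject_id: str = "",
) -> NodeTimeSeries:
    """Average voxel series within each parcel, on kept frames only.

    ``voxel_series`` holds one row per in-mask voxel, in the C-order of
    the parcellation's in-mask voxels (the order produced by indexing a
    4-D volume with the boolean mask).
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    labels_flat = parcellation.labels[parcellation.labels > 0]
    if voxel_series.shape[0] != labels_flat.size:
        raise ValueError(
            f"voxel series has {voxel_series.shape[0]} rows but the "
            f"parcellation has {labels_flat.size} in-mask voxels"
        )
    if censor is not None:
        if len(censor.keep) != voxel_series.shape[1]:
            raise ValueError("censor mask length does not match frame count")
        voxel_series = voxel_series[:, censor.keep]
    n_nodes = parcellation.n_nodes
    out = np.empty((n_nodes, voxel_series.shape[1]))
    for node in range(1, n_nodes + 1):
        rows = labels_flat == node
        if not rows.any():
            raise ValueError(f"node {node} has no voxels in the subject's coverage")
        out[node - 1] = voxel_series[rows].mean(axis=0)
    return NodeTimeSeries(out, subject_id=subject_id)


def correlation_matrix(ts: NodeTimeSeries) -> ConnMatrix:
    """Pearson correlation between node series, Fisher r-to-z transformed.

    r values are clipped to +/-(1 - 1e-15) before atanh so duplicated
    signals stay finite; the diagonal is zeroed.
    """
    if ts.n_frames < 3:
        raise ValueError("need at least 3 kept frames to correlate")
    sd = ts.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node(s): {(dead + 1).tolist()}")
    r = np.corrcoef(ts.values)
    z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnMatrix(z, subject_id=ts.subject_id)


def n_edges_at_sparsity(n_nodes: int, sparsity: float) -> int:
    """Edge count at a sparsity level: round(s * N(N-1)/2)."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    return int(round(sparsity * max_edges))


def edge_ranking(c: ConnMatrix, by_magnitude: bool = False) -> np.ndarray:
    """Deterministic strongest-first edge order as (k, 2) node-index pairs.

    Edges are ranked by signed z (strongest positive first) by default,
    or by |z| with ``by_magnitude``; ties at any value break toward the
    lexicographically lowest (i, j) pair so grid thresholds nest.
    """
    n = c.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = c.z[iu, ju]
    if by_magnitude:
        w = np.abs(w)
    order = np.lexsort((ju, iu, -w))
    return np.column_stack((iu[order], ju[order]))


def binarize_at_sparsity(
    c: ConnMatrix, s: float, by_magnitude: bool = False
) -> BinaryGraph:
    """Keep the round(s * N(N-1)/2) strongest edges of a connectome."""
    if not 0 < s < 1:
        raise ValueError("sparsity must lie strictly between 0 and 1")
    k = n_edges_at_sparsity(c.n_nodes, s)
    ranked = edge_ranking(c, by_magnitude=by_magnitude)
    if k > ranked.shape[0]:
        raise ValueError(f"requested {k} edges but only {ranked.shape[0]} available")
    adj = np.zeros((c.n_nodes, c.n_nodes), dtype=bool)
    top = ranked[:k]
    adj[top[:, 0], top[:, 1]] = True
    adj |= adj.T
    return BinaryGraph(adj, sparsity=s)
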