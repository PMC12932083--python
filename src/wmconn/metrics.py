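"""Binary-graph topological properties, null normalization, sparsity sweeps.

Ten global properties (clustering Cp, characteristic path length Lp,
global/local efficiency, assortativity, synchronizability, hierarchy,
and the null-normalized gamma, lambda, sigma) and six nodal properties
(degree, betweenness, clustering, efficiency, path length, local
efficiency) are computed on binary undirected graphs, swept across a
sparsity grid, and summarized by the trapezoidal area under each curve.

Path-length quantities use the harmonic-mean convention
(Lp = 1 / Eglobal), which stays finite on disconnected graphs — the
situation at the sparse end of the grid; the mean-over-connected-pairs
alternative is available via ``path_convention``.

Small-world normalization divides Cp and Lp by their means over
degree-preserving Maslov-Sneppen rewired null networks:
gamma = Cp/Cp_null, lambda = Lp/Lp_null, sigma = gamma/lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .connectome import BinaryGraph, ConnMatrix, binarize_at_sparsity
from .nulls import rewire_null

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "MetricCurve",
    "NullSpec",
    "SubjectCurves",
    "shortest_path_matrix",
    "global_metrics",
    "nodal_metrics",
    "small_world_normalize",
    "auc_trapezoid",
    "metric_curves",
    "validate_sparsity_range",
    "default_sparsity_grid",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = (
    "cp", "lp", "e_global", "e_local", "alpha",
    "s_sync", "beta_hier", "gamma", "lambda", "sigma",
)
NODAL_METRIC_NAMES = ("dc", "bc", "ncp", "ne", "nlp", "nle")


def default_sparsity_grid(
    lo: float = 0.07, hi: float = 0.30, step: float = 0.01
) -> np.ndarray:
    """The standard sparsity grid 0.07..0.30 in steps of 0.01."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


@dataclass(frozen=True)
class GlobalMetrics:
    cp: float
    lp: float
    e_global: float
    e_local: float
    alpha: float
    s_sync: float
    beta_hier: float
    gamma: float = float("nan")
    lambda_: float = float("nan")
    sigma: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "cp": self.cp, "lp": self.lp, "e_global": self.e_global,
            "e_local": self.e_local, "alpha": self.alpha, "s_sync": self.s_sync,
            "beta_hier": self.beta_hier, "gamma": self.gamma,
            "lambda": self.lambda_, "sigma": self.sigma,
        }


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node property arrays, all length N."""

    dc: np.ndarray
    bc: np.ndarray
    ncp: np.ndarray
    ne: np.ndarray
    nlp: np.ndarray
    nle: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "dc": self.dc, "bc": self.bc, "ncp": self.ncp,
            "ne": self.ne, "nlp": self.nlp, "nle": self.nle,
        }


@dataclass(frozen=True)
class NullSpec:
    """How many degree-preserving rewired nulls to use, and how thoroughly."""

    n_nulls: int = 100
    n_swaps_per_edge: int = 10
    seed: int | None = None


def shortest_path_matrix(g: BinaryGraph) -> np.ndarray:
    """All-pairs minimum hop counts; inf across components, 0 on the diagonal."""
    return _csgraph_sp(
        csr_matrix(g.adjacency), method="D", unweighted=True, directed=False
    )


def _triangles(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(np.float64)
    return np.einsum("ij,jk,ki->i", a, a, a) / 2.0


def _node_clustering(adj: np.ndarray) -> np.ndarray:
    k = adj.sum(axis=0).astype(float)
    t = _triangles(adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncp = np.where(k >= 2, 2.0 * t / (k * (k - 1.0)), 0.0)
    return ncp


def _efficiency_from_dist(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def _global_efficiency(adj: np.ndarray) -> float:
    dist = _csgraph_sp(csr_matrix(adj), method="D", unweighted=True, directed=False)
    return _efficiency_from_dist(dist)


def _nodal_efficiency(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def _local_efficiency_per_node(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = _global_efficiency(sub)
    return out


def _assortativity(adj: np.ndarray) -> float:
    """Newman degree-degree Pearson correlation over edge endpoints.

    Regular graphs (zero degree variance over edges) return 0 by
    convention so cohort tables stay finite.
    """
    k = adj.sum(axis=0).astype(float)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    if iu.size == 0:
        return 0.0
    x, y = k[iu], k[ju]
    m = float(iu.size)
    num = (x * y).mean() - ((x + y) / 2.0).mean() ** 2
    den = ((x**2 + y**2) / 2.0).mean() - ((x + y) / 2.0).mean() ** 2
    if den <= 1e-15:
        return 0.0
    return float(num / den)


def _synchronizability(adj: np.ndarray) -> float:
    deg = adj.sum(axis=0).astype(float)
    lap = np.diag(deg) - adj.astype(float)
    eig = np.linalg.eigvalsh(lap)
    if eig[-1] <= 1e-12:
        return 0.0
    lam2 = eig[1]
    return float(max(lam2, 0.0) / eig[-1])


def _hierarchy(adj: np.ndarray) -> float:
    """beta: minus the log-log OLS slope of node clustering on degree."""
    k = adj.sum(axis=0).astype(float)
    ncp = _node_clustering(adj)
    usable = (k >= 2) & (ncp > 0)
    if usable.sum() < 3:
        warnings.warn("hierarchy undefined (<3 usable nodes); returning 0", stacklevel=3)
        return 0.0
    logk = np.log(k[usable])
    logc = np.log(ncp[usable])
    if np.ptp(logk) < 1e-12:
        warnings.warn("hierarchy undefined (regular graph); returning 0", stacklevel=3)
        return 0.0
    slope = np.polyfit(logk, logc, 1)[0]
    return float(-slope)


def cp_lp(g: BinaryGraph, path_convention: str = "harmonic") -> tuple[float, float]:
    """Clustering coefficient and characteristic path length only.

    The cheap pair needed per null network during small-world
    normalization.
    """
    adj = g.adjacency
    cp = float(_node_clustering(adj).mean())
    dist = shortest_path_matrix(g)
    e_glob = _efficiency_from_dist(dist)
    lp = _char_path_length(dist, e_glob, path_convention)
    return cp, lp


def _char_path_length(dist: np.ndarray, e_glob: float, convention: str) -> float:
    if convention == "harmonic":
        return float(1.0 / e_glob) if e_glob > 0 else float("inf")
    if convention == "connected-mean":
        off = dist[~np.eye(dist.shape[0], dtype=bool)]
        finite = off[np.isfinite(off)]
        return float(finite.mean()) if finite.size else float("inf")
    raise ValueError(f"unknown path convention {convention!r}")


def global_metrics(g: BinaryGraph, path_convention: str = "harmonic") -> GlobalMetrics:
    """The seven unnormalized global properties of a binary graph.

    gamma/lambda/sigma stay NaN here; they require null networks
    (see :func:`small_world_normalize`).
    """
    adj = g.adjacency
    if g.n_nodes == 0 or g.n_edges == 0:
        raise ValueError("global metrics require a non-empty graph")
    dist = shortest_path_matrix(g)
    e_glob = _efficiency_from_dist(dist)
    return GlobalMetrics(
        cp=float(_node_clustering(adj).mean()),
        lp=_char_path_length(dist, e_glob, path_convention),
        e_global=e_glob,
        e_local=float(_local_efficiency_per_node(adj).mean()),
        alpha=_assortativity(adj),
        s_sync=_synchronizability(adj),
        beta_hier=_hierarchy(adj),
    )


def nodal_metrics(
    g: BinaryGraph, path_convention: str = "harmonic", normalized_bc: bool = False
) -> NodalMetrics:
    """The six per-node properties of a binary graph.

    Betweenness is Brandes' fraction-of-shortest-paths count,
    unnormalized by default to match common toolbox output.
    """
    adj = g.adjacency
    dist = shortest_path_matrix(g)
    ne = _nodal_efficiency(dist)
    # isolated nodes (ne = 0) report nlp = 0 by convention: they carry no
    # path information and the value keeps cohort tables finite
    if path_convention == "harmonic":
        with np.errstate(divide="ignore"):
            nlp = np.where(ne > 0, 1.0 / ne, 0.0)
    else:
        finite = np.where(np.isfinite(dist), dist, np.nan)
        np.fill_diagonal(finite, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            nlp = np.nan_to_num(np.nanmean(finite, axis=1), nan=0.0)
    graph = nx.from_numpy_array(adj)
    bc = nx.betweenness_centrality(graph, normalized=normalized_bc)
    return NodalMetrics(
        dc=adj.sum(axis=0).astype(int),
        bc=np.array([bc[i] for i in range(g.n_nodes)]),
        ncp=_node_clustering(adj),
        ne=ne,
        nlp=nlp,
        nle=_local_efficiency_per_node(adj),
    )


def small_world_normalize(
    g: BinaryGraph,
    n_nulls: int,
    n_swaps_per_edge: int = 10,
    seed: int | None = None,
    path_convention: str = "harmonic",
) -> tuple[float, float, float]:
    """gamma, lambda, sigma of a graph against degree-preserving nulls."""
    if n_nulls < 1:
        raise ValueError("need at least one null network")
    cp, lp = cp_lp(g, path_convention)
    seq = np.random.SeedSequence(seed)
    null_cp = np.empty(n_nulls)
    null_lp = np.empty(n_nulls)
    for i, child in enumerate(seq.spawn(n_nulls)):
        null = rewire_null(g, n_swaps_per_edge, seed=int(child.generate_state(1)[0] % (2**31)))
        null_cp[i], null_lp[i] = cp_lp(null, path_convention)
    mean_cp, mean_lp = null_cp.mean(), null_lp.mean()
    if mean_cp <= 0 or mean_lp <= 0 or not np.isfinite(mean_lp):
        raise ValueError("degenerate null networks: cannot normalize")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return gamma, lam, gamma / lam


@dataclass(frozen=True)
class MetricCurve:
    """A metric traced over the sparsity grid, with its trapezoidal AUC."""

    sparsity_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.sparsity_grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")
        if values.shape[-1] != grid.size:
            raise ValueError("values length must match the grid")
        object.__setattr__(self, "sparsity_grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def auc(self) -> float | np.ndarray:
        return auc_trapezoid(self.sparsity_grid, self.values)


def auc_trapezoid(grid: np.ndarray, values: np.ndarray):
    """Composite-trapezoid area of metric values over the sparsity grid.

    A single-point grid has no interval and integrates to 0 (warned).
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.size < 2:
        warnings.warn("AUC over a single-point grid is 0", stacklevel=2)
        return 0.0 if values.ndim == 1 else np.zeros(values.shape[0])
    out = np.trapezoid(values, grid, axis=-1)
    return float(out) if values.ndim == 1 else out


@dataclass(frozen=True)
class SubjectCurves:
    """All global and nodal metric curves of one subject's connectome."""

    subject_id: str
    sparsity_grid: np.ndarray
    global_curves: dict[str, MetricCurve]
    nodal_curves: dict[str, MetricCurve]  # values shaped (n_nodes, n_sparsities)

    def global_auc(self) -> dict[str, float]:
        return {name: c.auc for name, c in self.global_curves.items()}

    def nodal_auc(self) -> dict[str, np.ndarray]:
        return {name: c.auc for name, c in self.nodal_curves.items()}


def metric_curves(
    c: ConnMatrix,
    grid: np.ndarray | None = None,
    null_spec: NullSpec | None = None,
    path_convention: str = "harmonic",
    compute_nodal: bool = True,
) -> SubjectCurves:
    """Binarize a connectome across the grid and trace every metric.

    When ``null_spec`` is given, gamma/lambda/sigma are computed at each
    sparsity against freshly rewired degree-preserving nulls; otherwise
    those three curves are omitted.
    """
    grid = default_sparsity_grid() if grid is None else np.asarray(grid, dtype=float)
    n_s = grid.size
    gvals: dict[str, np.ndarray] = {name: np.empty(n_s) for name in GLOBAL_METRIC_NAMES}
    if null_spec is None:
        for name in ("gamma", "lambda", "sigma"):
            del gvals[name]
    nvals: dict[str, np.ndarray] = {}
    if compute_nodal:
        nvals = {name: np.empty((c.n_nodes, n_s)) for name in NODAL_METRIC_NAMES}
    children = (
        np.random.SeedSequence(null_spec.seed).spawn(n_s)
        if null_spec is not None
        else [None] * n_s
    )
    for si, s in enumerate(grid):
        g = binarize_at_sparsity(c, float(s))
        gm = global_metrics(g, path_convention)
        if null_spec is not None:
            gamma, lam, sigma = small_world_normalize(
                g,
                null_spec.n_nulls,
                null_spec.n_swaps_per_edge,
                seed=int(children[si].generate_state(1)[0] % (2**31)),
                path_convention=path_convention,
            )
            gm = replace(gm, gamma=gamma, lambda_=lam, sigma=sigma)
        for name, val in gm.as_dict().items():
            if name in gvals:
                gvals[name][si] = val
        if compute_nodal:
            nm = nodal_metrics(g, path_convention)
            for name, arr in nm.as_dict().items():
                nvals[name][:, si] = arr
    return SubjectCurves(
        subject_id=c.subject_id,
        sparsity_grid=grid,
        global_curves={k: MetricCurve(grid, v) for k, v in gvals.items()},
        nodal_curves={k: MetricCurve(grid, v) for k, v in nvals.items()},
    )


def validate_sparsity_range(
    conns: list[ConnMatrix],
    grid: np.ndarray | None = None,
    n_nulls: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int | None = None,
    log_base: float = 10.0,
    sigma_floor: float = 1.0,
):
    """Check the two admissibility criteria of a sparsity grid.

    Per sparsity: the minimum over subjects of the mean binary degree
    must exceed 2 x log(N) (log base configurable; both log10 and ln
    readings are in circulation), and the minimum over subjects of
    small-worldness sigma must exceed ``sigma_floor``.
    """
    import pandas as pd

    grid = default_sparsity_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or not conns:
        return pd.DataFrame(
            columns=["sparsity", "min_mean_degree", "degree_bound",
                     "degree_ok", "min_sigma", "sigma_ok"]
        )
    n = conns[0].n_nodes
    bound = 2.0 * np.log(n) / np.log(log_base)
    rows = []
    for si, s in enumerate(grid):
        degs, sigmas = [], []
        for ci, c in enumerate(conns):
            g = binarize_at_sparsity(c, float(s))
            degs.append(g.degrees.mean())
            child = np.random.SeedSequence((seed or 0) * 1000003 + si * 1009 + ci)
            _, _, sigma = small_world_normalize(
                g, n_nulls, n_swaps_per_edge,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            sigmas.append(sigma)
        rows.append(
            {
                "sparsity": float(s),
                "min_mean_degree": float(min(degs)),
                "degree_bound": float(bound),
                "degree_ok": bool(min(degs) > bound),
                "min_sigma": float(min(sigmas)),
                "sigma_ok": bool(min(sigmas) > sigma_floor),
            }
        )
    return pd.DataFrame(rows)
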