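import networkx as nx
import numpy as np
import pytest

from wmconn.connectome import BinaryGraph, ConnMatrix, binarize_at_sparsity
from wmconn.metrics import (
    auc_trapezoid,
    cp_lp,
    default_sparsity_grid,
    global_metrics,
    nodal_metrics,
    shortest_path_matrix,
    small_world_normalize,
    validate_sparsity_range,
)
from wmconn.nulls import rewire_null

from . import oracles


def _graph(adj):
    return BinaryGraph(np.asarray(adj, bool))


def _path3():
    adj = np.zeros((3, 3), bool)
    adj[0, 1] = adj[1, 2] = True
    return _graph(adj | adj.T)


class TestClosedForms:
    def test_complete_graph_unit_metrics(self):
        g = _graph(~np.eye(5, dtype=bool))
        m = global_metrics(g)
        assert m.cp == pytest.approx(1.0)
        assert m.lp == pytest.approx(1.0)
        assert m.e_global == pytest.approx(1.0)
        assert m.e_local == pytest.approx(1.0)
        assert m.s_sync == pytest.approx(1.0)  # Laplacian spectrum {0, N,...,N}

    def test_star_graph_perfectly_disassortative(self):
        adj = np.zeros((6, 6), bool)
        adj[0, 1:] = True
        g = _graph(adj | adj.T)
        assert global_metrics(g).alpha == pytest.approx(-1.0)

    def test_path_graph_betweenness(self):
        m = nodal_metrics(_path3())
        np.testing.assert_allclose(m.bc, [0.0, 1.0, 0.0])

    def test_triangle_clustering(self):
        g = _graph(~np.eye(3, dtype=bool))
        np.testing.assert_allclose(nodal_metrics(g).ncp, 1.0)

    def test_path_graph_distances(self):
        d = shortest_path_matrix(_path3())
        assert d[0, 2] == 2.0

    def test_disconnected_distances_infinite(self):
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = True
        adj[2, 3] = adj[3, 2] = True
        d = shortest_path_matrix(_graph(adj))
        assert np.isinf(d[0, 2])
        assert global_metrics(_graph(adj)).s_sync == 0.0


class TestOracleEquivalence:
    def test_distance_matrix_matches_floyd_warshall(self, random_graphs):
        for g in random_graphs:
            np.testing.assert_array_equal(
                shortest_path_matrix(g), oracles.floyd_warshall(g.adjacency)
            )

    def test_global_metrics_match_enumeration(self, random_graphs):
        for g in random_graphs:
            m = global_metrics(g)
            adj = g.adjacency
            assert m.cp == pytest.approx(
                oracles.clustering_by_enumeration(adj).mean(), abs=1e-12
            )
            assert m.e_global == pytest.approx(
                oracles.global_efficiency_by_pairs(adj), abs=1e-12
            )
            assert m.e_local == pytest.approx(
                oracles.local_efficiency_by_pairs(adj), abs=1e-12
            )

    def test_nodal_metrics_match_enumeration(self, random_graphs):
        for g in random_graphs:
            m = nodal_metrics(g)
            adj = g.adjacency
            np.testing.assert_allclose(
                m.ncp, oracles.clustering_by_enumeration(adj), atol=1e-12
            )
            np.testing.assert_allclose(
                m.ne, oracles.nodal_efficiency_by_pairs(adj), atol=1e-12
            )
            np.testing.assert_array_equal(m.dc, adj.sum(axis=0))

    def test_betweenness_matches_path_enumeration(self, random_graphs):
        small = [g for g in random_graphs if g.n_nodes <= 10][:10]
        assert small
        for g in small:
            np.testing.assert_allclose(
                nodal_metrics(g).bc,
                oracles.betweenness_by_path_enumeration(g.adjacency),
                atol=1e-10,
            )

    def test_assortativity_matches_networkx(self, random_graphs):
        for g in random_graphs:
            deg = g.degrees
            if np.ptp(deg) == 0:
                continue
            expected = nx.degree_assortativity_coefficient(
                nx.from_numpy_array(g.adjacency)
            )
            if not np.isfinite(expected):
                continue
            assert global_metrics(g).alpha == pytest.approx(expected, abs=1e-10)


class TestPathConventions:
    def test_lp_is_inverse_global_efficiency(self, random_graphs):
        for g in random_graphs[:10]:
            m = global_metrics(g)
            assert m.lp == pytest.approx(1.0 / m.e_global, abs=1e-12)

    def test_connected_mean_convention_on_path(self):
        m = global_metrics(_path3(), path_convention="connected-mean")
        assert m.lp == pytest.approx((1 + 1 + 2) / 3)


class TestNulls:
    def test_degree_sequence_preserved_any_seed(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((64, 64))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        g = binarize_at_sparsity(ConnMatrix(z), 0.15)
        for seed in range(10):
            null = rewire_null(g, 10, seed=seed)
            np.testing.assert_array_equal(null.degrees, g.degrees)
            assert null.n_edges == g.n_edges

    def test_complete_graph_has_no_legal_swap(self):
        g = _graph(~np.eye(6, dtype=bool))
        null = rewire_null(g, 10, seed=0)
        np.testing.assert_array_equal(null.adjacency, g.adjacency)

    def test_rewiring_destroys_lattice_clustering(self):
        g = _graph(nx.to_numpy_array(nx.watts_strogatz_graph(64, 6, 0.0)) > 0)
        lattice_cp, _ = cp_lp(g)
        assert lattice_cp == pytest.approx(0.6)  # ring lattice closed form
        hits = 0
        for seed in range(100):
            null_cp, _ = cp_lp(rewire_null(g, 10, seed=seed))
            hits += null_cp < 0.5 * lattice_cp
        assert hits >= 95

    def test_seeded_determinism(self):
        g = _graph(nx.to_numpy_array(nx.gnm_random_graph(32, 100, seed=1)) > 0)
        a = rewire_null(g, 10, seed=5)
        b = rewire_null(g, 10, seed=5)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestSmallWorld:
    def test_self_normalization_is_unity(self):
        # zero swap attempts leave every "null" identical to the graph
        g = _graph(nx.to_numpy_array(nx.gnm_random_graph(20, 60, seed=2)) > 0)
        gamma, lam, sigma = small_world_normalize(g, 5, n_swaps_per_edge=0, seed=0)
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_watts_strogatz_is_small_world(self):
        g = _graph(nx.to_numpy_array(nx.watts_strogatz_graph(128, 10, 0.1, seed=4)) > 0)
        gamma, lam, sigma = small_world_normalize(g, 20, 10, seed=0)
        assert sigma > 1.0
        assert gamma > 1.0
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)

    def test_fixed_seed_reproducible(self):
        g = _graph(nx.to_numpy_array(nx.gnm_random_graph(40, 150, seed=3)) > 0)
        a = small_world_normalize(g, 10, 10, seed=11)
        b = small_world_normalize(g, 10, 10, seed=11)
        assert a == b


class TestAUC:
    def test_constant_curve_rectangle(self):
        grid = default_sparsity_grid()
        assert auc_trapezoid(grid, np.full(grid.size, 3.0)) == pytest.approx(
            0.23 * 3.0
        )

    def test_linear_curve_closed_form(self):
        grid = default_sparsity_grid()
        # integral of v(s) = s over [0.07, 0.30] is (0.30^2 - 0.07^2)/2
        assert auc_trapezoid(grid, grid.copy()) == pytest.approx(
            (0.30**2 - 0.07**2) / 2.0
        )

    def test_single_point_grid_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="single-point"):
            assert auc_trapezoid(np.array([0.1]), np.array([5.0])) == 0.0


class TestSweeps:
    def test_global_efficiency_monotone_in_sparsity(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal((48, 48))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        c = ConnMatrix(z)
        values = [
            global_metrics(binarize_at_sparsity(c, s)).e_global
            for s in default_sparsity_grid(0.07, 0.30, 0.05)
        ]
        assert np.all(np.diff(values) >= 0)

    def test_validate_sparsity_range_degree_arithmetic(self):
        rng = np.random.default_rng(1)
        spec_z = rng.standard_normal((128, 128))
        spec_z = (spec_z + spec_z.T) / 2
        np.fill_diagonal(spec_z, 0)
        conns = [ConnMatrix(spec_z)]
        report10 = validate_sparsity_range(
            conns, np.array([0.10]), n_nulls=2, seed=0, log_base=10
        )
        # mean degree 0.10 x 127 = 12.7 exceeds 2 log10(128) = 4.21
        assert report10.min_mean_degree[0] == pytest.approx(12.7, abs=0.01)
        assert report10.degree_bound[0] == pytest.approx(4.214, abs=0.001)
        assert bool(report10.degree_ok[0])
        report_e = validate_sparsity_range(
            conns, np.array([0.07]), n_nulls=2, seed=0, log_base=np.e
        )
        # under the natural-log reading 8.89 < 9.70: criterion fails
        assert report_e.min_mean_degree[0] == pytest.approx(8.89, abs=0.01)
        assert report_e.degree_bound[0] == pytest.approx(9.704, abs=0.001)
        assert not bool(report_e.degree_ok[0])

    def test_empty_grid_gives_empty_report(self):
        assert validate_sparsity_range([], np.array([])).empty


class TestDegenerateInputs:
    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            global_metrics(_graph(np.zeros((4, 4), bool)))

    def test_regular_graph_hierarchy_warns_zero(self):
        g = _graph(nx.to_numpy_array(nx.watts_strogatz_graph(16, 4, 0.0)) > 0)
        with pytest.warns(UserWarning, match="hierarchy"):
            assert global_metrics(g).beta_hier == 0.0
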