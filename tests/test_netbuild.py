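"""Network generators, block configurations, and analytic special cases."""

import itertools

import numpy as np
import pytest

from cascnet import (
    ExtremeConfigSpec,
    Network,
    R_C_UNIFORM,
    cascading_C,
    clustering_coefficient,
    critical_R,
    extreme_Rc,
    extreme_crossover,
    karate_club,
    leontief,
    make_extreme,
    make_network,
    scale_free_Rc_meanfield,
)
from cascnet.netbuild import _extreme_C_of_r, extreme_connection_fraction


class TestGenerators:
    def test_er_directed_hits_requested_density_exactly(self):
        net = make_network("er", N=50, c=0.1, R0=0.2, directed=True, seed=1)
        assert net.n_edges == round(0.1 * 50 * 50)

    def test_er_undirected_is_symmetric(self):
        net = make_network("er", N=40, c=0.1, R0=0.2, directed=False, seed=2)
        assert np.array_equal(net.A, net.A.T)
        assert net.n_edges == 2 * round(0.1 * 40 * 40 / 2)

    @pytest.mark.parametrize("model", ["ba", "ws", "ring"])
    def test_undirected_models_symmetric_with_target_degree(self, model):
        net = make_network(model, N=60, k=6, R0=0.2, seed=3)
        assert np.array_equal(net.A, net.A.T)
        degrees = (net.A > 0).sum(axis=1)
        if model == "ring":
            assert np.all(degrees == 6)
        else:
            assert degrees.mean() == pytest.approx(6, rel=0.15)

    def test_edge_weight_normalizes_average_column_sum_to_R0(self):
        R0 = 0.3
        for model, kw in [("er", dict(N=50, c=0.1, directed=True)),
                          ("ring", dict(N=50, k=6)), ("ba", dict(N=50, k=6))]:
            net = make_network(model, R0=R0, seed=4, **kw)
            assert net.A.sum(axis=0).mean() == pytest.approx(R0, rel=1e-12)

    def test_er_full_density_equals_uniform_minus_diagonal(self):
        er = make_network("er", N=12, c=1.0 - 1.0 / 12, R0=0.2, directed=True, seed=0)
        uni = make_network("uniform", N=12, R0=0.2)
        assert np.allclose(er.A, uni.A)

    def test_karate_graph_dimensions(self):
        G = karate_club()
        assert G.number_of_nodes() == 34
        assert G.number_of_edges() == 78
        net = make_network("karate", R0=0.2)
        assert net.n_nodes == 34 and net.n_edges == 156

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_network("smallworldish", N=10, c=0.1)


class TestExtremeConfigs:
    def test_hand_written_blocks_small_n(self):
        w = lambda spec, R0: R0 / (spec.N * extreme_connection_fraction(spec))
        spec = ExtremeConfigSpec("i", 5, 3)
        A = make_extreme(spec, R0=0.1).A
        a = w(spec, 0.1)
        expected = np.zeros((5, 5))
        expected[:3, :3] = a
        np.fill_diagonal(expected, 0)
        assert np.allclose(A, expected)

        spec = ExtremeConfigSpec("iii", 6, 2)
        A = make_extreme(spec, R0=0.1).A
        a = w(spec, 0.1)
        expected = np.zeros((6, 6))
        expected[:2, 2:] = a
        assert np.allclose(A, expected)

        spec = ExtremeConfigSpec("iv", 4)
        A = make_extreme(spec, R0=0.1).A
        assert np.all(A[np.triu_indices(4)] == 0)
        assert np.all(A[np.tril_indices(4, -1)] > 0)

    def test_full_group_reduces_to_uniform(self):
        # M = N: every off-diagonal pair connected, weight R0/(N c) with the
        # diagonal-inclusive convention c = M^2/N^2 = 1
        spec = ExtremeConfigSpec("i", 20, 20)
        net = make_extreme(spec, R0=0.2)
        expected = np.full((20, 20), 0.2 / 20)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(net.A, expected)

    def test_directed_bipartite_is_nilpotent_with_neumann_leontief(self):
        net = make_extreme(ExtremeConfigSpec("iii", 10, 4), R0=0.3)
        assert np.allclose(net.A @ net.A, 0.0)
        assert np.allclose(leontief(net), np.eye(10) + net.A)

    @pytest.mark.parametrize("kind,M", [("i", 10), ("ii", 8), ("iii", 12), ("iv", 0)])
    def test_block_evaluation_matches_dense(self, kind, M):
        spec = ExtremeConfigSpec(kind, 30, M)
        C_of_r, _pole = _extreme_C_of_r(spec, rho=1.0)
        dense = cascading_C(make_extreme(spec, R0=0.15, rho=1.0))
        assert C_of_r(0.15) == pytest.approx(dense, abs=1e-10)

    @pytest.mark.parametrize("kind,M", [("i", 12), ("ii", 10)])
    def test_block_Rc_matches_dense_critical_R(self, kind, M):
        spec = ExtremeConfigSpec(kind, 30, M)
        rc_block = extreme_Rc(spec)
        net = make_extreme(spec, R0=0.2, rho=1.0)
        rc_dense = critical_R(net, at_R0=0.2)
        assert rc_block == pytest.approx(rc_dense, abs=1e-5)

    def test_crossover_location_of_clique_vs_clique_plus_periphery(self):
        c_star = extreme_crossover(N=400, n_grid=60)
        assert 0.1 < c_star < 0.35  # coarse sanity; the N=1000 value is ~0.21

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ExtremeConfigSpec("v", 10, 2)
        with pytest.raises(ValueError):
            ExtremeConfigSpec("i", 10, 11)


class TestScaleFreeMeanField:
    def test_equal_degrees_reduce_to_uniform_value(self):
        assert scale_free_Rc_meanfield(np.full(200, 8.0)) == pytest.approx(
            R_C_UNIFORM, abs=1e-6
        )

    def test_critical_point_decreases_with_system_size_for_ba(self):
        import networkx as nx

        rcs = []
        for N in (250, 500, 1000, 2000):
            G = nx.barabasi_albert_graph(N, 3, seed=1)
            deg = np.array([d for _, d in G.degree()], dtype=float)
            rcs.append(scale_free_Rc_meanfield(deg))
        assert np.all(np.diff(rcs) < 0)

    def test_heterogeneity_lowers_critical_point(self):
        hom = scale_free_Rc_meanfield(np.full(100, 6.0))
        het = scale_free_Rc_meanfield(np.concatenate([np.full(90, 4.0), np.full(10, 24.0)]))
        assert het < hom

    def test_nonpositive_degrees_rejected(self):
        with pytest.raises(ValueError):
            scale_free_Rc_meanfield(np.array([3.0, 0.0, 2.0]))


class TestClustering:
    def test_triangle_and_star(self):
        tri = Network((np.ones((3, 3)) - np.eye(3)) * 0.1, 1.0)
        assert clustering_coefficient(tri) == pytest.approx(1.0)
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 0.1
        assert clustering_coefficient(Network(star, 1.0)) == 0.0

    def test_matches_brute_force_triangle_count(self, rng):
        n = 25
        mask = np.triu(rng.random((n, n)) < 0.25, 1)
        A = (mask | mask.T).astype(float) * 0.05
        net = Network(A, 1.0)
        got = clustering_coefficient(net)
        # brute force: per-node triangles over connected pairs of neighbours
        adj = A > 0
        local = []
        for v in range(n):
            nb = np.nonzero(adj[v])[0]
            if len(nb) < 2:
                local.append(0.0)
                continue
            tri = sum(adj[a, b] for a, b in itertools.combinations(nb, 2))
            local.append(tri / (len(nb) * (len(nb) - 1) / 2))
        assert got == pytest.approx(np.mean(local), abs=1e-12)
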