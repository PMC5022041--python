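"""Leontief machinery, the cascading statistic C, and exchange updates."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from cascnet import (
    C_CRITICAL,
    R_C_UNIFORM,
    Network,
    cascade_report,
    cascading_C,
    critical_R,
    exact_exchange_deltaC,
    exchange_score_H,
    leontief,
    make_network,
    mean_rates,
)


def uniform_net(N, R0, rho=0.5, diagonal=True):
    A = np.full((N, N), R0 / N)
    if not diagonal:
        np.fill_diagonal(A, 0.0)
    return Network(A, rho, allow_self_loops=diagonal)


class TestLeontief:
    def test_empty_interaction_gives_identity(self):
        net = Network(np.zeros((4, 4)), 1.0)
        assert np.array_equal(leontief(net), np.eye(4))

    def test_uniform_column_sums_geometric_series(self):
        R0 = 0.3
        L = leontief(uniform_net(50, R0))
        assert np.allclose(L.sum(axis=0), 1.0 / (1.0 - R0))

    def test_nilpotent_chain_is_finite_sum(self, chain2):
        L = leontief(chain2)
        assert np.allclose(L, np.array([[1.0, 0.0], [0.4, 1.0]]))

    def test_inverse_identity_holds(self, er_net):
        L = leontief(er_net)
        n = er_net.n_nodes
        assert np.allclose(L @ (np.eye(n) - er_net.A), np.eye(n), atol=1e-10)
        assert np.all(L >= -1e-12)

    def test_supercritical_matrix_rejected_with_spectral_radius(self):
        net = uniform_net(10, 1.2)
        with pytest.raises(ValueError, match="spectral radius"):
            leontief(net)


class TestMeanRates:
    def test_no_interaction_returns_base_rates(self):
        rho = np.array([0.1, 0.5, 2.0])
        net = Network(np.zeros((3, 3)), rho)
        assert np.allclose(mean_rates(net), rho)

    def test_uniform_equal_rates_match_univariate_formula(self):
        R0 = 0.25
        lam = mean_rates(uniform_net(30, R0, rho=0.5))
        assert np.allclose(lam, 0.5 / (1.0 - R0))

    def test_chain_rates_compose(self, chain2):
        lam = mean_rates(chain2)
        assert lam[0] == pytest.approx(0.5)
        assert lam[1] == pytest.approx(0.2 + 0.4 * 0.5)


class TestCascadingC:
    def test_poisson_superposition_has_C_one(self):
        net = Network(np.zeros((5, 5)), np.array([0.2, 1.0, 0.3, 0.5, 2.0]))
        rep = cascade_report(net)
        assert rep.C == pytest.approx(1.0)
        assert not rep.nonstationary

    @pytest.mark.parametrize("N", [10, 100, 1000])
    def test_uniform_closed_form_with_diagonal(self, N):
        R0 = 0.2
        assert cascading_C(uniform_net(N, R0)) == pytest.approx(1.0 / (1.0 - R0) ** 2)

    def test_uniform_without_diagonal_agrees_to_order_one_over_N(self):
        R0 = 0.2
        C = cascading_C(uniform_net(400, R0, diagonal=False))
        assert C == pytest.approx(1.0 / (1.0 - R0) ** 2, rel=2.0 / 400)

    def test_critical_value_two_at_uniform_critical_point(self):
        assert cascading_C(uniform_net(100, R_C_UNIFORM)) == pytest.approx(C_CRITICAL, abs=1e-9)

    def test_permutation_invariance(self, er_net, rng):
        perm = rng.permutation(er_net.n_nodes)
        net2 = Network(er_net.A[np.ix_(perm, perm)], er_net.rho[perm])
        assert cascading_C(net2) == pytest.approx(cascading_C(er_net), abs=1e-10)

    def test_base_rate_scale_invariance(self, er_net):
        scaled = Network(er_net.A, er_net.rho * 37.0)
        assert cascading_C(scaled) == pytest.approx(cascading_C(er_net), abs=1e-10)

    def test_all_zero_base_rates_rejected(self):
        with pytest.raises(ValueError, match="base rates"):
            cascade_report(Network(np.zeros((3, 3)), 0.0))


class TestCriticalR:
    def test_uniform_network_hits_known_point(self):
        net = uniform_net(100, 0.2)
        assert critical_R(net, at_R0=0.2) == pytest.approx(R_C_UNIFORM, abs=1e-6)

    def test_builder_form_agrees_with_linear_form(self, er_net):
        from cascnet.network import Network as Net

        r1 = critical_R(er_net, at_R0=0.2)
        r2 = critical_R(lambda r: Net(er_net.A * (r / 0.2), er_net.rho))
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_empty_network_has_no_transition(self):
        net = Network(np.zeros((5, 5)), 1.0)
        assert np.isnan(critical_R(net, at_R0=0.2))


class TestExchangeScore:
    def test_uncoupled_network_gives_flat_score(self):
        rho = 0.7
        net = Network(np.zeros((6, 6)), rho)
        H = exchange_score_H(cascade_report(net), net)
        assert np.allclose(H, 2.0 * rho)

    def test_score_permutes_with_node_labels(self, er_net, rng):
        H = exchange_score_H(cascade_report(er_net), er_net)
        perm = rng.permutation(er_net.n_nodes)
        net2 = Network(er_net.A[np.ix_(perm, perm)], er_net.rho[perm])
        H2 = exchange_score_H(cascade_report(net2), net2)
        assert np.allclose(H2, H[np.ix_(perm, perm)], atol=1e-10)

    def test_score_differences_track_exact_exchange_effect(self, rng):
        """H ranks exchanges consistently with the exact Delta-C (rank corr > 0.9)."""
        net = make_network("er", N=40, c=0.15, R0=0.25, rho=0.5, directed=True, seed=3)
        rep = cascade_report(net)
        L = leontief(net)
        H = exchange_score_H(rep, net)
        rows, cols = np.nonzero(net.A)
        zr, zc = np.nonzero((net.A == 0) & ~np.eye(net.n_nodes, dtype=bool))
        d_exact, d_first = [], []
        for _ in range(150):
            a = rng.integers(len(rows))
            b = rng.integers(len(zr))
            eo, ei = (rows[a], cols[a]), (zr[b], zc[b])
            d_exact.append(exact_exchange_deltaC(net, eo, ei, rep, L))
            d_first.append(H[ei] - H[eo])
        assert spearmanr(d_exact, d_first).statistic > 0.9


class TestExactExchange:
    def test_null_exchange_changes_nothing(self, er_net):
        i, j = map(int, np.argwhere(er_net.A > 0)[0])
        assert exact_exchange_deltaC(er_net, (i, j), (i, j)) == 0.0

    def test_matches_dense_recomputation(self):
        net = make_network("er", N=20, c=0.2, R0=0.25, rho=0.5, directed=True, seed=11)
        rep = cascade_report(net)
        L = leontief(net)
        rows, cols = np.nonzero(net.A)
        zr, zc = np.nonzero((net.A == 0) & ~np.eye(20, dtype=bool))
        for t in range(25):
            eo = (int(rows[t]), int(cols[t]))
            ei = (int(zr[3 * t]), int(zc[3 * t]))
            dC = exact_exchange_deltaC(net, eo, ei, rep, L)
            A2 = net.A.copy()
            w = A2[eo]
            A2[eo] = 0.0
            A2[ei] = w
            brute = cascading_C(Network(A2, net.rho)) - rep.C
            assert dC == pytest.approx(brute, abs=1e-10)

    def test_undirected_pair_exchange_matches_dense(self):
        net = make_network("er", N=20, c=0.2, R0=0.2, rho=0.5, directed=False, seed=4)
        rep = cascade_report(net)
        L = leontief(net)
        iu, ju = np.nonzero(np.triu(net.A, 1))
        zi, zj = np.nonzero(np.triu((net.A == 0), 1))
        for t in range(15):
            eo = (int(iu[t]), int(ju[t]))
            ei = (int(zi[2 * t]), int(zj[2 * t]))
            dC = exact_exchange_deltaC(net, eo, ei, rep, L)
            A2 = net.A.copy()
            w = A2[eo]
            A2[eo[0], eo[1]] = A2[eo[1], eo[0]] = 0.0
            A2[ei[0], ei[1]] = A2[ei[1], ei[0]] = w
            brute = cascading_C(Network(A2, net.rho, directed=False)) - rep.C
            assert dC == pytest.approx(brute, abs=1e-10)

    def test_constraint_violations_raise(self, er_net):
        i, j = map(int, np.argwhere(er_net.A > 0)[0])
        with pytest.raises(ValueError, match="self-loop"):
            exact_exchange_deltaC(er_net, (i, j), (2, 2))
        i2, j2 = map(int, np.argwhere(er_net.A > 0)[1])
        with pytest.raises(ValueError, match="occupied"):
            exact_exchange_deltaC(er_net, (i, j), (i2, j2))
        zi, zj = map(int, np.argwhere((er_net.A == 0) & ~np.eye(er_net.n_nodes, dtype=bool))[0])
        with pytest.raises(ValueError, match="no connection"):
            exact_exchange_deltaC(er_net, (zi, zj), (i, j))
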