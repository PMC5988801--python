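from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from netcurv.ollivier import (
    ProbabilityMeasure,
    neighbor_measure,
    ollivier_all_edges,
    ollivier_edge,
    ollivier_vertex,
    wasserstein1,
)

from _oracles import exact_measure, w1_dual_bound, w1_flow_oracle
from conftest import random_connected_graph


def exact_neighbor_measure(g, x, alpha=Fraction(0)):
    """Fraction-mass version of the walk measure, for the flow oracle."""
    nbrs = list(g[x])
    masses = [Fraction(alpha)] + [(1 - Fraction(alpha)) / len(nbrs)] * len(nbrs)
    return exact_measure([x] + nbrs, masses)


class TestNeighborMeasure:
    def test_star_center_uniform_on_leaves(self, star5):
        m = neighbor_measure(star5, 0, alpha=0.0)
        assert set(m.support) == {0, 1, 2, 3, 4, 5}
        assert m.mass[0] == 0.0
        assert np.allclose(m.mass[1:], 1 / 5)

    def test_leaf_is_point_mass_at_hub(self, star5):
        m = neighbor_measure(star5, 1, alpha=0.0)
        assert m.support == [1, 0]
        assert np.allclose(m.mass, [0.0, 1.0])

    def test_lazy_walk_split(self):
        g = nx.star_graph(4)
        m = neighbor_measure(g, 0, alpha=0.5)
        assert m.mass[0] == 0.5 and np.allclose(m.mass[1:], 0.125)

    def test_isolated_vertex_raises(self):
        g = nx.Graph()
        g.add_node(0)
        with pytest.raises(ValueError, match="isolated"):
            neighbor_measure(g, 0)

    def test_invalid_masses_rejected(self):
        with pytest.raises(ValueError):
            ProbabilityMeasure([0, 1], [0.6, 0.6])
        with pytest.raises(ValueError):
            ProbabilityMeasure([0, 0], [0.5, 0.5])


class TestWasserstein:
    def test_identical_measures_cost_zero(self, star5):
        m = neighbor_measure(star5, 0)
        w1, _ = wasserstein1(star5, m, m)
        assert w1 == pytest.approx(0.0, abs=1e-9)

    def test_point_masses_cost_the_distance(self):
        g = nx.path_graph(4)
        w1, plan = wasserstein1(
            g, ProbabilityMeasure([0], [1.0]), ProbabilityMeasure([3], [1.0])
        )
        assert w1 == pytest.approx(3.0)
        assert plan.entries == {(0, 3): pytest.approx(1.0)}

    def test_k3_edge_measures(self):
        g = nx.complete_graph(3)
        w1, _ = wasserstein1(
            g, neighbor_measure(g, 0, 0.0), neighbor_measure(g, 1, 0.0)
        )
        assert w1 == pytest.approx(0.5)

    def test_disconnected_supports_raise(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="different components"):
            wasserstein1(
                g, ProbabilityMeasure([0], [1.0]), ProbabilityMeasure([2], [1.0])
            )

    def test_plan_satisfies_marginals(self, rng):
        g = random_connected_graph(rng, n_max=10)
        nodes = sorted(g.nodes)
        mu = neighbor_measure(g, nodes[0], 0.25)
        nu = neighbor_measure(g, nodes[-1], 0.25)
        w1, plan = wasserstein1(g, mu, nu)
        for s, m in zip(mu.support, mu.mass):
            assert sum(v for (a, _), v in plan.entries.items() if a == s) == pytest.approx(m, abs=1e-9)
        for t, m in zip(nu.support, nu.mass):
            assert sum(v for (_, b), v in plan.entries.items() if b == t) == pytest.approx(m, abs=1e-9)

    def test_metric_axioms_on_random_measures(self, rng):
        """Symmetry and triangle inequality of W1 over a fixed component."""
        for _ in range(5):
            g = random_connected_graph(rng, n_max=15)
            nodes = sorted(g.nodes)
            picks = rng.choice(nodes, size=3, replace=False)
            ms = [neighbor_measure(g, int(v), alpha=0.3) for v in picks]
            w = {}
            for i in range(3):
                for j in range(3):
                    w[i, j], _ = wasserstein1(g, ms[i], ms[j])
            for i in range(3):
                assert w[i, i] == pytest.approx(0.0, abs=1e-9)
                for j in range(3):
                    assert w[i, j] == pytest.approx(w[j, i], abs=1e-9)
                    for k in range(3):
                        assert w[i, j] <= w[i, k] + w[k, j] + 1e-9

    def test_lp_equals_flow_oracle_and_dual(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, n_max=10)
            u, v = next(iter(g.edges))
            w1, _ = wasserstein1(
                g, neighbor_measure(g, u, 0.0), neighbor_measure(g, v, 0.0)
            )
            oracle = w1_flow_oracle(
                g, exact_neighbor_measure(g, u), exact_neighbor_measure(g, v)
            )
            dual = w1_dual_bound(
                g, exact_neighbor_measure(g, u), exact_neighbor_measure(g, v)
            )
            assert w1 == pytest.approx(float(oracle), abs=1e-8)
            assert w1 == pytest.approx(dual, abs=1e-7)


class TestOllivierEdge:
    @pytest.mark.parametrize(
        "g, e, expected",
        [
            (nx.star_graph(5), (0, 1), 0.0),
            (nx.complete_graph(3), (0, 1), 0.5),
            (nx.path_graph(3), (0, 1), 0.0),
        ],
    )
    def test_worked_examples(self, g, e, expected):
        assert ollivier_edge(g, e, alpha=0.0) == pytest.approx(expected)

    def test_double_star_bridge_is_negative(self, double_star):
        assert ollivier_edge(double_star, (0, 10), alpha=0.0) < 0

    def test_curvature_bounds_at_alpha_zero(self, rng):
        for _ in range(5):
            g = random_connected_graph(rng, n_max=15)
            for e in g.edges:
                k = ollivier_edge(g, e, alpha=0.0)
                assert -2.0 - 1e-9 <= k <= 1.0 + 1e-9

    def test_complete_graph_curvature_grows_with_n(self):
        k3 = ollivier_edge(nx.complete_graph(3), (0, 1), 0.0)
        prev = k3
        for n in (10, 15, 20):
            kn = ollivier_edge(nx.complete_graph(n), (0, 1), 0.0)
            assert kn > k3
            assert kn >= prev - 1e-12
            prev = kn

    def test_label_permutation_invariance(self, rng):
        g = random_connected_graph(rng, n_max=12)
        perm = dict(zip(sorted(g.nodes), rng.permutation(sorted(g.nodes)).tolist()))
        h = nx.relabel_nodes(g, perm)
        for u, v in g.edges:
            assert ollivier_edge(g, (u, v), 0.25) == pytest.approx(
                ollivier_edge(h, (perm[u], perm[v]), 0.25), abs=1e-9
            )


class TestBatchAndVertex:
    def test_k3_table(self):
        t = ollivier_all_edges(nx.complete_graph(3), alpha=0.0)
        assert all(v == pytest.approx(0.5) for v in t.values.values())

    def test_star_table_all_zero(self, star5):
        t = ollivier_all_edges(star5, alpha=0.0)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in t.values.values())

    def test_k2_single_edge(self):
        t = ollivier_all_edges(nx.path_graph(2), alpha=0.0)
        assert t[(0, 1)] == pytest.approx(0.0, abs=1e-9)

    def test_disconnected_input_rejected(self):
        with pytest.raises(ValueError, match="largest_connected_component"):
            ollivier_all_edges(nx.Graph([(0, 1), (2, 3)]))

    def test_batch_agrees_with_per_edge(self, rng):
        g = random_connected_graph(rng, n_max=12)
        t = ollivier_all_edges(g, alpha=0.5)
        for e in g.edges:
            assert t[e] == pytest.approx(ollivier_edge(g, e, 0.5), abs=1e-8)

    def test_vertex_curvature(self, star5):
        g3 = nx.complete_graph(3)
        v3 = ollivier_vertex(g3, ollivier_all_edges(g3, 0.0))
        assert v3[0] == pytest.approx(1.0)
        vs = ollivier_vertex(star5, ollivier_all_edges(star5, 0.0))
        assert vs[0] == pytest.approx(0.0, abs=1e-9)

    def test_handshake_conservation(self, rng):
        g = random_connected_graph(rng, n_max=15)
        t = ollivier_all_edges(g, alpha=0.5)
        vt = ollivier_vertex(g, t)
        assert sum(vt.values.values()) == pytest.approx(2 * sum(t.values.values()))
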