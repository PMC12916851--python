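import networkx as nx
import numpy as np
import pytest

import oracles
from mosqnet import add_nodes, attack, benjamini_hochberg, compare_addition, \
    pct_disconnection_point
from mosqnet.robustness import AdditionCurve, STRATEGIES, _connected_pairs


def signed(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, r=0.7, sign=1, absweight=0.7)
    return g


def star(k):
    return signed([("hub", f"l{i}") for i in range(k)])


class TestAttack:
    def test_star_hub_removal_disconnects_everything(self):
        curve = attack(star(5), "degree")
        assert curve.connectivity_loss[1] == pytest.approx(1.0)
        assert pct_disconnection_point(curve, 0.8) == pytest.approx(1 / 6)

    def test_complete_graph_first_removal(self):
        g = signed([(i, j) for i in range(4) for j in range(i + 1, 4)])
        for strategy in STRATEGIES:
            curve = attack(g, strategy, seed=0)
            assert curve.connectivity_loss[1] == pytest.approx(1 - 3 / 6)

    def test_edgeless_network_rejected(self):
        with pytest.raises(ValueError):
            attack(nx.Graph(), "degree")

    def test_monotone_and_boundary_conditions(self, graph_factory):
        rng = np.random.default_rng(0)
        for _ in range(15):
            g = graph_factory(rng)
            if g.number_of_edges() == 0:
                continue
            for strategy in STRATEGIES:
                c = attack(g, strategy, seed=7)
                assert c.connectivity_loss[0] == 0.0
                assert c.connectivity_loss[-1] == pytest.approx(1.0)
                assert (np.diff(c.connectivity_loss) >= -1e-12).all()

    def test_pair_counting_matches_bfs_oracle(self, graph_factory):
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = graph_factory(rng, n_max=10)
            if g.number_of_edges() == 0:
                continue
            curve = attack(g, "betweenness")
            # replay the recorded removal order against the naive oracle
            nodes = sorted(g.nodes)
            pairs0 = oracles.connected_pairs(
                (nx.to_numpy_array(g, nodelist=nodes) != 0).astype(float))
            h = nx.Graph(g)
            for k, victim in enumerate(curve.removal_order, start=1):
                h.remove_node(victim)
                rem = sorted(h.nodes)
                adj = (nx.to_numpy_array(h, nodelist=rem) != 0).astype(float) \
                    if rem else np.zeros((0, 0))
                expect = 1 - oracles.connected_pairs(adj) / pairs0
                assert curve.connectivity_loss[k] == pytest.approx(expect)

    def test_degree_equals_cascading_on_star(self):
        c1 = attack(star(6), "degree")
        c2 = attack(star(6), "cascading")
        np.testing.assert_allclose(c1.connectivity_loss,
                                   c2.connectivity_loss)

    def test_random_strategy_seeded(self):
        g = star(5)
        c1 = attack(g, "random", seed=5)
        c2 = attack(g, "random", seed=5)
        np.testing.assert_allclose(c1.connectivity_loss,
                                   c2.connectivity_loss)


class TestDisconnectionPoint:
    def test_level_zero_is_zero(self):
        assert pct_disconnection_point(attack(star(4), "degree"), 0.0) == 0.0

    def test_unreachable_level_gives_one(self):
        g = signed([("a", "b")])
        curve = attack(g, "degree")
        curve.connectivity_loss = np.array([0.0, 0.5, 0.7])
        assert pct_disconnection_point(curve, 0.8) == 1.0


class TestAddition:
    def test_k3_plus_one_node(self):
        g = signed([(0, 1), (1, 2), (0, 2)])
        curves = add_nodes(g, 1, reps=1, seed=0)
        assert curves[0].lcc[-1] == 4
        assert curves[0].apl[-1] == pytest.approx(8 / 6)

    def test_no_addition_returns_base_metrics(self):
        g = signed([(0, 1), (1, 2), (0, 2)])
        curves = add_nodes(g, 0, reps=1, seed=0)
        assert curves[0].lcc[0] == 3
        assert curves[0].apl[0] == pytest.approx(1.0)

    def test_lcc_non_decreasing(self):
        g = signed([(0, 1), (1, 2), (3, 4)])
        for curve in add_nodes(g, 30, reps=3, seed=2):
            assert (np.diff(curve.lcc) >= 0).all()

    def test_disjoint_triangles_eventually_bridge(self):
        g = signed([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        curves = add_nodes(g, 40, reps=5, seed=3)
        assert any(c.lcc[-1] == 6 + 40 for c in curves) or \
            any(c.lcc[-1] > 6 for c in curves)


class TestCompareAddition:
    def make_curves(self, values):
        return [AdditionCurve(replicate=0, n_added=np.arange(len(values)),
                              lcc=np.array(values, float),
                              apl=np.array(values, float))]

    def test_identical_series_p_one(self):
        a = self.make_curves(range(10))
        out = compare_addition(a, a, seed=0)
        assert (out["p"] == 1.0).all()
        assert (out["mean_diff"] == 0.0).all()

    def test_shifted_series_matches_sign_enumeration(self):
        a = self.make_curves(np.arange(10) + 1.0)
        b = self.make_curves(np.arange(10))
        out = compare_addition(a, b, seed=0)
        expected = oracles.wilcoxon_exact_two_sided(np.ones(10))
        assert out["p"].iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(2 / 2 ** 10)

    def test_bootstrap_ci_brackets_mean(self):
        rng = np.random.default_rng(4)
        a = self.make_curves(rng.normal(5, 1, size=20))
        b = self.make_curves(rng.normal(3, 1, size=20))
        out = compare_addition(a, b, seed=1)
        row = out.iloc[0]
        assert row["ci_low"] <= row["mean_diff"] <= row["ci_high"]


def test_benjamini_hochberg_hand_example():
    np.testing.assert_allclose(benjamini_hochberg(np.array([0.01, 0.02, 0.04])),
                               [0.03, 0.03, 0.04])


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(5)
    p = rng.uniform(size=12)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(benjamini_hochberg(p), ref, atol=1e-12)
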