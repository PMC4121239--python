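import math

import networkx as nx
import numpy as np
import pytest

from noderole import indicators
from noderole.synthetic import complete, cycle, star

import oracles


class TestDegree:
    def test_star(self, star5):
        d = indicators.degree(star5)
        assert d[0] == 4 and all(d[v] == 1 for v in range(1, 5))

    def test_relative(self, star5):
        d = indicators.degree(star5, relative=True)
        assert d[0] == pytest.approx(1.0)
        assert d[1] == pytest.approx(0.25)

    def test_single_node_relative(self):
        g = nx.Graph()
        g.add_node("x")
        assert indicators.degree(g, relative=True)["x"] == 0.0


class TestClustering:
    def test_triangle(self, triangle):
        assert all(v == 1.0 for v in indicators.clustering(triangle).values())

    def test_star_hub(self, star5):
        assert indicators.clustering(star5)[0] == 0.0

    def test_k4_minus_edge(self):
        g = complete(4)
        g.remove_edge(0, 1)
        c = indicators.clustering(g)
        # nodes 0,1 have degree 2 with their two neighbors adjacent
        assert c[0] == pytest.approx(1.0)
        # nodes 2,3 keep degree 3; 2 of 3 neighbor pairs are edges
        assert c[2] == pytest.approx(2 / 3)


class TestBetweenness:
    def test_path_middle(self):
        b = indicators.betweenness(nx.path_graph(3))
        assert b[1] == pytest.approx(1.0)

    def test_star_hub(self, star5):
        assert indicators.betweenness(star5)[0] == pytest.approx(6.0)

    def test_matches_enumeration_on_random_graph(self):
        g = nx.gnp_random_graph(8, 0.4, seed=7)
        expected = oracles.brute_betweenness(g)
        got = indicators.betweenness(g)
        for v in g.nodes():
            assert got[v] == pytest.approx(expected[v], abs=1e-12)


class TestEgoBetweenness:
    def test_star_hub_equals_global(self, star5):
        assert indicators.ego_betweenness(star5)[0] == pytest.approx(6.0)

    def test_double_star_bridge(self, dstar):
        assert indicators.ego_betweenness(dstar)["v7"] == pytest.approx(1.0)

    def test_pendant_is_zero(self):
        g = nx.path_graph(4)
        eb = indicators.ego_betweenness(g)
        assert eb[0] == 0.0 and eb[3] == 0.0


class TestEigenvector:
    def test_triangle_all_equal_one(self, triangle):
        ev = indicators.eigenvector(triangle)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in ev.values())

    def test_star_closed_form(self, star5):
        # principal eigenvalue 2; hub component twice each leaf's
        ev = indicators.eigenvector(star5)
        assert ev[0] == pytest.approx(1.0)
        for leaf in range(1, 5):
            assert ev[leaf] == pytest.approx(0.5, abs=1e-9)

    def test_star_ego_equals_global(self, star5):
        # the star is its own two-layer ego network from every node
        g, e = indicators.eigenvector(star5), indicators.eigenvector(star5, ego=True)
        for v in star5.nodes():
            assert e[v] == pytest.approx(g[v], abs=1e-8)

    def test_edgeless_graph_warns_and_zeroes(self):
        g = nx.empty_graph(3)
        with pytest.warns(UserWarning):
            ev = indicators.eigenvector(g)
        assert set(ev.values()) == {0.0}


class TestCloseness:
    def test_star(self, star5):
        c = indicators.closeness(star5)
        assert c[0] == pytest.approx(1.0)
        assert c[1] == pytest.approx(4 / 7)

    def test_path_middle(self):
        assert indicators.closeness(nx.path_graph(3))[1] == pytest.approx(1.0)

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_edge(1, 2)
        g.add_node(3)
        assert indicators.closeness(g)[3] == 0.0


class TestInformationCentrality:
    @pytest.mark.parametrize("reg", ["identity", "ones"])
    def test_symmetric_graphs_constant(self, reg):
        for g in (complete(2), complete(3)):
            vals = list(indicators.information_centrality(g, regularization=reg).values())
            assert max(vals) - min(vals) < 1e-12
            assert all(v > 0 for v in vals)

    @pytest.mark.parametrize("reg", ["identity", "ones"])
    def test_star_matches_inverse_oracle(self, star5, reg):
        got = indicators.information_centrality(star5, regularization=reg)
        expected = oracles.inverse_information_centrality(star5, reg)
        for v in star5.nodes():
            assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_disconnected_per_component(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.complete_graph(3))
        got = indicators.information_centrality(g)
        expected = oracles.inverse_information_centrality(g)
        for v in g.nodes():
            assert got[v] == pytest.approx(expected[v], abs=1e-9)


class TestStructuralHoles:
    def test_star_hub(self, star5):
        sh = indicators.structural_holes(star5)
        assert sh.loc[0, "effective_size"] == pytest.approx(4.0)
        assert sh.loc[0, "efficiency"] == pytest.approx(1.0)
        assert sh.loc[0, "constraint"] == pytest.approx(0.25)
        assert sh.loc[0, "hierarchy"] == pytest.approx(0.0, abs=1e-12)

    def test_k3_effective_size(self, triangle):
        sh = indicators.structural_holes(triangle)
        assert sh["effective_size"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_pendant_matches_oracle(self):
        g = nx.path_graph(4)
        got = indicators.structural_holes(g)
        expected = oracles.burt_measures(g)
        for v in g.nodes():
            assert got.loc[v, "efficiency"] == pytest.approx(expected[v][1], abs=1e-9)
            assert got.loc[v, "constraint"] == pytest.approx(expected[v][2], abs=1e-9)

    def test_isolated_node_warns_and_zeroes(self):
        g = nx.Graph()
        g.add_edge(1, 2)
        g.add_node(3)
        with pytest.warns(UserWarning):
            sh = indicators.structural_holes(g)
        assert sh.loc[3].tolist() == [0.0, 0.0, 0.0, 0.0]


class TestIndicatorTable:
    def test_columns_and_values(self, star5):
        t = indicators.indicator_table(star5, ["degree", "ego_betweenness"])
        assert list(t.columns) == ["degree", "ego_betweenness"]
        assert t.loc[0, "degree"] == 4
        assert t.loc[0, "ego_betweenness"] == pytest.approx(6.0)

    def test_empty_subset(self, star5):
        t = indicators.indicator_table(star5, [])
        assert t.shape == (5, 0)

    def test_unknown_indicator(self, star5):
        with pytest.raises(KeyError):
            indicators.indicator_table(star5, ["degree", "nope"])

    def test_full_table_matches_single_ops(self):
        g = nx.gnp_random_graph(10, 0.4, seed=3)
        t = indicators.indicator_table(g)
        assert list(t.columns) == list(indicators.VOCABULARY)
        assert not t.isna().any().any()
        deg = indicators.degree(g)
        ev = indicators.eigenvector(g)
        sh = indicators.structural_holes(g)
        for v in g.nodes():
            assert t.loc[v, "degree"] == deg[v]
            assert t.loc[v, "eigenvector"] == pytest.approx(ev[v])
            assert t.loc[v, "hierarchy"] == pytest.approx(sh.loc[v, "hierarchy"])

    @pytest.mark.parametrize("make", [lambda: cycle(6), lambda: complete(5)])
    def test_vertex_transitive_constant_columns(self, make):
        t = indicators.indicator_table(make())
        for col in t.columns:
            assert t[col].max() - t[col].min() < 1e-8, col

    def test_adding_leaf_is_monotone(self, karate):
        base = indicators.structural_holes(karate)
        v = 0
        g2 = karate.copy()
        g2.add_edge(v, "new_leaf")
        grown = indicators.structural_holes(g2)
        assert g2.degree(v) == karate.degree(v) + 1
        assert grown.loc[v, "effective_size"] >= base.loc[v, "effective_size"]
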