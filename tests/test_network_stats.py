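"""Graph statistics against independent enumeration oracles."""

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from symptomnet.network_stats import (
    all_pairs_shortest_paths,
    betweenness_rank_agreement,
    degree_tail_fit,
    er_expectations,
    giant_component,
    mc_walk_betweenness,
    random_walk_betweenness,
    sample_er_graphs,
    small_world_index,
    summarize,
    transitivity,
)

from conftest import brute_force_transitivity, enumerate_geodesics


def random_connected_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g


class TestGiantComponent:
    def test_two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(3))
        sub, frac = giant_component(g)
        assert sub.number_of_nodes() == 5
        assert frac == pytest.approx(0.625)

    def test_fixture_is_connected(self, fixture_graph):
        sub, frac = giant_component(fixture_graph)
        assert frac == 1.0
        assert sub.number_of_nodes() == 14

    def test_tie_break_lexicographic(self):
        g = nx.Graph([("b", "c"), ("a", "d")])
        sub, _ = giant_component(g)
        assert set(sub.nodes) == {"a", "d"}

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            giant_component(nx.Graph())

    def test_printed_giant_fraction(self):
        # a 439-node graph whose giant component has 208 nodes
        g = nx.path_graph(208)
        g.add_nodes_from(range(1000, 1231))  # 231 isolates
        _, frac = giant_component(g)
        assert frac == pytest.approx(208 / 439)
        assert round(100 * frac, 1) == 47.4


class TestTransitivity:
    def test_triangle(self):
        assert transitivity(nx.complete_graph(3)) == pytest.approx(1.0)

    def test_path_has_zero_clustering(self):
        assert transitivity(nx.path_graph(3)) == pytest.approx(0.0)

    def test_fixture_value(self, fixture_graph):
        # 164 triangles, 592 centered triples, by exhaustive enumeration
        assert brute_force_transitivity(fixture_graph) == pytest.approx(3 * 164 / 592)
        assert transitivity(fixture_graph) == pytest.approx(3 * 164 / 592)

    def test_no_length_two_paths_is_error(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            transitivity(g)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_triple_enumeration_on_random_graphs(self, seed):
        g = random_connected_graph(n=int(8 + seed % 5), p=0.4, seed=seed)
        assert transitivity(g) == pytest.approx(brute_force_transitivity(g))


class TestShortestPaths:
    def test_four_cycle_lengths_and_counts(self):
        nodes, lengths, counts = all_pairs_shortest_paths(nx.cycle_graph(4))
        idx = {v: i for i, v in enumerate(nodes)}
        assert lengths[idx[0], idx[1]] == 1
        assert lengths[idx[0], idx[2]] == 2
        assert counts[idx[0], idx[2]] == 2  # two geodesics around the cycle

    def test_complete_graph(self):
        nodes, lengths, counts = all_pairs_shortest_paths(nx.complete_graph(5))
        off = ~np.eye(5, dtype=bool)
        assert (lengths[off] == 1).all()
        assert (counts[off] == 1).all()

    def test_disconnected_pairs_marked_unreachable(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        nodes, lengths, _ = all_pairs_shortest_paths(g)
        idx = {v: i for i, v in enumerate(nodes)}
        assert np.isnan(lengths[idx["a"], idx["c"]])

    def test_fixture_core_to_core_geodesics(self, fixture_graph):
        # core-MDE to core-GAD: length 2 with one geodesic per bridge symptom
        nodes, lengths, counts = all_pairs_shortest_paths(fixture_graph)
        idx = {v: i for i, v in enumerate(nodes)}
        assert lengths[idx["mDep"], idx["gAnx"]] == 2
        assert counts[idx["mDep"], idx["gAnx"]] == 4

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(int(rng.integers(4, 10)), 0.45, seed=seed)
        oracle_len, oracle_cnt = enumerate_geodesics(g)
        nodes, lengths, counts = all_pairs_shortest_paths(g)
        idx = {v: i for i, v in enumerate(nodes)}
        for (u, v), ell in oracle_len.items():
            got = lengths[idx[u], idx[v]]
            if ell is None:
                assert np.isnan(got)
            else:
                assert got == ell
                assert counts[idx[u], idx[v]] == oracle_cnt[(u, v)]


class TestSummarize:
    def test_fixture_summary(self, fixture_graph):
        s = summarize(fixture_graph)
        assert s.n == 14 and s.m == 66
        assert s.avg_path_length == pytest.approx(Fraction(116, 91))
        assert s.mean_geodesic_count == pytest.approx(Fraction(166, 91))
        assert s.mean_degree * s.n == pytest.approx(2 * s.m)
        assert s.density * math.comb(s.n, 2) == pytest.approx(s.m)

    def test_complete_graph_summary(self):
        s = summarize(nx.complete_graph(4))
        assert s.mean_degree == 3
        assert s.avg_path_length == 1
        assert s.mean_geodesic_count == 1

    def test_disconnected_input_rejected(self):
        with pytest.raises(ValueError, match="giant_component"):
            summarize(nx.Graph([("a", "b"), ("c", "d")]))


class TestERExpectations:
    def test_printed_values_at_giant_component_size(self):
        e = er_expectations(208, 1949)
        assert round(e.c_rnd, 2) == 0.09
        assert round(e.l_rnd, 2) == 2.12

    def test_dense_limit_sane(self):
        n = 10
        e = er_expectations(n, math.comb(n, 2))
        assert e.c_rnd == pytest.approx((n - 1) / n)
        assert e.l_rnd < 1.6

    def test_subcritical_mean_degree_rejected(self):
        with pytest.raises(ValueError):
            er_expectations(100, 50)

    def test_sampled_graphs_agree_with_closed_form(self):
        e = er_expectations(1000, 5000)
        out = sample_er_graphs(1000, 5000, reps=30, seed=0)
        assert out["L"].mean() == pytest.approx(e.l_rnd, rel=0.02)


class TestSampleER:
    def test_deterministic_under_seed(self):
        a = sample_er_graphs(50, 120, reps=5, seed=9)
        b = sample_er_graphs(50, 120, reps=5, seed=9)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_mean_swi_near_one(self):
        out = sample_er_graphs(208, 1949, reps=60, seed=3)
        se = out["SWI"].std(ddof=1) / np.sqrt(len(out["SWI"]))
        assert abs(out["SWI"].mean() - 1) < 3 * se + 0.05

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError):
            sample_er_graphs(5, 11, reps=1, seed=0)


class TestSmallWorldIndex:
    def test_published_worked_example(self):
        res = small_world_index(0.68, 2.6, 208, 1949)
        assert round(res.swi, 1) == 6.2
        assert res.swi > 3  # conservative small-world criterion

    def test_identity_at_baseline(self):
        e = er_expectations(208, 1949)
        assert small_world_index(e.c_rnd, e.l_rnd, 208, 1949).swi == pytest.approx(1.0)

    @given(
        n=st.integers(20, 300),
        k=st.floats(2.0, 12.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_identity_property_over_valid_region(self, n, k):
        m = int(n * k / 2)
        if 2 * m / n <= 1.05 or m > n * (n - 1) // 2:
            return
        e = er_expectations(n, m)
        assert small_world_index(e.c_rnd, e.l_rnd, n, m).swi == pytest.approx(1.0)

    def test_zero_clustering_gives_zero(self):
        assert small_world_index(0.0, 2.0, 208, 1949).swi == 0.0


class TestDegreeTailFit:
    def test_geometric_tail_classified_exponential(self):
        rng = np.random.default_rng(1)
        deg = rng.geometric(0.15, size=500)
        assert degree_tail_fit(deg)["classification"] == "exponential"

    def test_pareto_tail_classified_power_law(self):
        rng = np.random.default_rng(2)
        deg = np.floor(rng.pareto(1.5, size=500) + 1).astype(int)
        assert degree_tail_fit(deg)["classification"] == "power-law"

    def test_constant_degrees_rejected(self):
        with pytest.raises(ValueError):
            degree_tail_fit([4] * 50)


class TestBetweenness:
    def test_star_center_maximal(self):
        g = nx.star_graph(5)
        bw = random_walk_betweenness(g)
        assert bw[0] > max(bw[i] for i in range(1, 6))

    def test_complete_graph_symmetric(self):
        bw = random_walk_betweenness(nx.complete_graph(4))
        vals = list(bw.values())
        assert max(vals) - min(vals) < 1e-12

    def test_path_graph_monotone_from_middle(self):
        bw = random_walk_betweenness(nx.path_graph(5))
        assert bw[2] > bw[1] > bw[0]
        assert bw[2] > bw[3] > bw[4]

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError):
            random_walk_betweenness(nx.Graph([("a", "b"), ("c", "d")]))

    def test_mc_path_middle_node_always_crossed(self):
        g = nx.path_graph(3)
        # walks restricted to the two endpoints: every walk passes node 1
        est = mc_walk_betweenness(g, walks=300, seed=0, pairs=[(0, 2), (2, 0)])
        assert est[1] >= 1.0
        assert est[0] == 0.0 and est[2] == 0.0  # endpoints excluded

    def test_mc_complete_graph_symmetric_within_error(self):
        est = mc_walk_betweenness(nx.complete_graph(4), walks=4000, seed=1)
        vals = np.array(list(est.values()))
        se = vals.std(ddof=1)
        assert vals.max() - vals.min() < 3 * se + 0.1

    def test_mc_agrees_with_exact_on_random_graphs(self):
        g = random_connected_graph(20, 0.25, seed=5)
        rho = betweenness_rank_agreement(g, walks=3000, seed=7)
        assert rho > 0.9

    def test_mc_converges_with_more_walks(self):
        g = random_connected_graph(12, 0.3, seed=8)
        exact = random_walk_betweenness(g)
        rhos = []
        for walks in (50, 5000):
            est = mc_walk_betweenness(g, walks, seed=2)
            rho, _ = spearmanr(
                [exact[v] for v in g.nodes], [est[v] for v in g.nodes]
            )
            rhos.append(rho)
        assert rhos[1] >= rhos[0]
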