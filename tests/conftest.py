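import networkx as nx
import pytest

from symptomnet.incidence_model import project_to_symptom_graph
from symptomnet.synthetic_data import mde_gad_fixture


@pytest.fixture(scope="session")
def fixture_table():
    table, _, _ = mde_gad_fixture()
    return table


@pytest.fixture(scope="session")
def fixture_rules():
    _, rules, _ = mde_gad_fixture()
    return rules


@pytest.fixture(scope="session")
def fixture_graph(fixture_table):
    return project_to_symptom_graph(fixture_table)


def enumerate_geodesics(graph):
    """Exhaustive shortest-path oracle: (lengths, counts) dicts by node pair.

    Enumerates every simple path between every pair and keeps the minimal
    length and the number of distinct minimal paths.  Only viable for tiny
    graphs; that is the point — it is independent of the BFS recursion
    used by the production code.
    """
    lengths, counts = {}, {}
    nodes = list(graph.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            best, n_best = None, 0
            for path in nx.all_simple_paths(graph, u, v):
                plen = len(path) - 1
                if best is None or plen < best:
                    best, n_best = plen, 1
                elif plen == best:
                    n_best += 1
            lengths[(u, v)] = best
            counts[(u, v)] = n_best
    return lengths, counts


def brute_force_transitivity(graph):
    """Triple-enumeration clustering oracle: 3·triangles / ordered-center triples."""
    from itertools import combinations

    triangles = sum(
        1
        for a, b, c in combinations(graph.nodes, 3)
        if graph.has_edge(a, b) and graph.has_edge(b, c) and graph.has_edge(a, c)
    )
    triples = sum(d * (d - 1) // 2 for _, d in graph.degree())
    if triples == 0:
        raise ValueError("no length-2 paths")
    return 3 * triangles / triples
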