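"""Static graph statistics: components, clustering, geodesics, degree-tail
classification, betweenness, random-graph baselines and the small-world index.

The small-world diagnosis compares the observed transitivity C and average
shortest path length L of the giant component against the expectations
C_rnd and L_rnd of an Erdős–Rényi graph with the same number of nodes and
edges:

    SWI = (C / C_rnd) / (L / L_rnd)

with C_rnd = <k>/n (the edge probability) and
L_rnd = (ln n - γ)/ln<k> + 1/2 (γ the Euler–Mascheroni constant).
An SWI of at least 3 is taken as the conservative small-world criterion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path
from scipy.stats import spearmanr

EULER_GAMMA = float(np.euler_gamma)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSummary:
    """Summary statistics of a connected graph.

    Attributes
    ----------
    n, m : int
        Node and edge counts.
    mean_degree : float
        2m/n, edges per node.
    density : float
        m divided by the n(n-1)/2 possible edges.
    transitivity : float
        Global clustering coefficient: 3·(triangles) / (paths of length 2).
    avg_path_length : float
        Mean geodesic length over all unordered node pairs (edges).
    mean_geodesic_count : float
        Mean number of distinct shortest paths per unordered pair.
    degree_sequence : tuple of int
    """

    n: int
    m: int
    mean_degree: float
    density: float
    transitivity: float
    avg_path_length: float
    mean_geodesic_count: float
    degree_sequence: tuple


@dataclass(frozen=True)
class ERExpectation:
    """Expected clustering and path length of a size-matched random graph."""

    c_rnd: float
    l_rnd: float


@dataclass(frozen=True)
class SmallWorldResult:
    """Small-world-ness index together with its four ingredients."""

    swi: float
    c: float
    l: float
    c_rnd: float
    l_rnd: float


def ordered_subgraph(graph: nx.Graph, nodes) -> nx.Graph:
    """Induced subgraph whose node order follows ``nodes`` exactly.

    ``networkx`` subgraph views iterate their node filter in set order,
    which varies across processes for string labels; simulations map
    random draws to nodes by position, so a stable order matters.
    """
    sub = nx.Graph()
    sub.add_nodes_from((n, dict(graph.nodes[n])) for n in nodes)
    keep = set(nodes)
    sub.add_edges_from(
        (u, v, d)
        for u in nodes
        for v, d in sorted(graph.adj[u].items(), key=lambda kv: str(kv[0]))
        if v in keep and str(u) < str(v)
    )
    return sub


def giant_component(graph: nx.Graph):
    """Largest connected component as an induced subgraph, plus node fraction.

    Ties between equally large components are broken by the
    lexicographically smallest member label.  Node order in the returned
    copy is lexicographic, so downstream results do not depend on hash
    order.

    Returns
    -------
    (networkx.Graph, float)
        The induced subgraph (a copy) and its share of the full node set.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph has no giant component")
    comps = [sorted(c, key=str) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), str(c[0])))
    biggest = comps[0]
    return ordered_subgraph(graph, biggest), len(biggest) / graph.number_of_nodes()


def transitivity(graph: nx.Graph) -> float:
    """Global clustering coefficient: 3·(#triangles) / (#paths of length 2).

    The denominator is the number of connected ordered-center triples,
    Σ_v C(deg v, 2).  Undefined (raises) when the graph has no path of
    length 2.
    """
    triples = sum(d * (d - 1) // 2 for _, d in graph.degree())
    if triples == 0:
        raise ValueError("transitivity undefined: graph has no paths of length 2")
    return nx.transitivity(graph)


def _adjacency(graph: nx.Graph):
    nodes = list(graph.nodes)
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None, format="csr")
    return nodes, a


def all_pairs_shortest_paths(graph: nx.Graph):
    """Geodesic lengths and geodesic counts for every node pair.

    Returns
    -------
    (nodes, lengths, counts)
        ``nodes``: node order; ``lengths``: float matrix of geodesic
        lengths with ``nan`` marking unreachable pairs and 0 on the
        diagonal; ``counts``: number of distinct shortest paths per pair
        (0 for unreachable pairs, 1 on the diagonal).

    Geodesic counts use the standard BFS path-count recursion
    σ(s,v) = Σ_{u ∈ pred(v)} σ(s,u).
    """
    nodes, a = _adjacency(graph)
    n = len(nodes)
    dist = _sp_shortest_path(a, method="D", unweighted=True)
    counts = np.zeros((n, n), dtype=float)
    indptr, indices = a.indptr, a.indices
    for s in range(n):
        d = dist[s]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        finite = np.isfinite(d)
        order = np.argsort(d[finite], kind="stable")
        reach = np.flatnonzero(finite)[order]
        for v in reach:
            if v == s:
                continue
            preds = indices[indptr[v]:indptr[v + 1]]
            on_geo = preds[d[preds] == d[v] - 1]
            sigma[v] = sigma[on_geo].sum()
        counts[s] = sigma
    lengths = np.where(np.isfinite(dist), dist, np.nan)
    return nodes, lengths, counts


def summarize(graph: nx.Graph) -> NetworkSummary:
    """Full summary of a connected graph.

    ``avg_path_length`` and ``mean_geodesic_count`` are averages over all
    unordered distinct pairs.  Disconnected input raises: restrict to the
    giant component first.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph):
        raise ValueError("graph is disconnected; apply giant_component first")
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    _, lengths, counts = all_pairs_shortest_paths(graph)
    iu = np.triu_indices(n, k=1)
    return NetworkSummary(
        n=n,
        m=m,
        mean_degree=2 * m / n,
        density=m / (n * (n - 1) / 2),
        transitivity=transitivity(graph),
        avg_path_length=float(lengths[iu].mean()) if n > 1 else 0.0,
        mean_geodesic_count=float(counts[iu].mean()) if n > 1 else 1.0,
        degree_sequence=tuple(sorted((d for _, d in graph.degree()), reverse=True)),
    )


def er_expectations(n: int, m: int) -> ERExpectation:
    """Closed-form C and L expectations for a G(n,m) random graph.

    C_rnd = <k>/n equals the edge probability; L_rnd uses the mean-field
    result (ln n - γ)/ln<k> + 1/2, valid above the percolation threshold
    <k> > 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    k = 2 * m / n
    if k <= 1:
        raise ValueError(f"mean degree {k:.3f} <= 1: path-length formula invalid")
    c_rnd = k / n
    l_rnd = (math.log(n) - EULER_GAMMA) / math.log(k) + 0.5
    return ERExpectation(c_rnd=c_rnd, l_rnd=l_rnd)


def small_world_index(c: float, l: float, n: int, m: int) -> SmallWorldResult:
    """SWI = (C/C_rnd)/(L/L_rnd) with the closed-form baselines at (n, m)."""
    if l <= 0:
        raise ValueError("average path length must be positive")
    exp = er_expectations(n, m)
    if c == 0:
        logger.warning("zero clustering: SWI is 0")
    return SmallWorldResult(
        swi=(c / exp.c_rnd) / (l / exp.l_rnd),
        c=c,
        l=l,
        c_rnd=exp.c_rnd,
        l_rnd=exp.l_rnd,
    )


def _giant_stats(graph: nx.Graph):
    """(C, L, n, m) of a graph's giant component, fast path via scipy."""
    sub, _ = giant_component(graph)
    n = sub.number_of_nodes()
    m = sub.number_of_edges()
    _, a = _adjacency(sub)
    dist = _sp_shortest_path(a, method="D", unweighted=True)
    iu = np.triu_indices(n, k=1)
    l = float(dist[iu].mean()) if n > 1 else 0.0
    return nx.transitivity(sub), l, n, m


def sample_er_graphs(n: int, m: int, reps: int, seed):
    """Sample G(n,m) random graphs and record (C, L, SWI) per replicate.

    Each replicate's statistics are computed on the sampled graph's giant
    component; the SWI baseline uses that component's own (n, m).

    Returns
    -------
    dict with arrays "C", "L", "SWI", each of length ``reps``.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    if m > n * (n - 1) // 2:
        raise ValueError("m exceeds the number of possible edges")
    rng = np.random.default_rng(seed)
    out = {"C": np.empty(reps), "L": np.empty(reps), "SWI": np.empty(reps)}
    for r in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        c, l, ng, mg = _giant_stats(g)
        out["C"][r] = c
        out["L"][r] = l
        out["SWI"][r] = small_world_index(c, l, ng, mg).swi
    return out


def degree_tail_fit(degree_sequence):
    """Classify a degree distribution's tail as exponential or power-law.

    Fits the log empirical survival function ln P(K > k) linearly against
    k (exponential tail) and against ln k (power-law tail) and classifies
    by coefficient of determination; a difference in R² below 0.01 is
    reported as "indeterminate".

    Returns
    -------
    dict with keys "classification", "r2_exponential", "r2_power_law",
    "slope_exponential", "slope_power_law".
    """
    deg = np.asarray(sorted(degree_sequence))
    if deg.size < 2 or len(np.unique(deg)) < 2:
        raise ValueError("degenerate (constant) degree sequence")
    ks = np.unique(deg)
    # survival P(K > k) at each distinct degree; drop zero-survival tail point
    surv = np.array([(deg > k).mean() for k in ks])
    keep = (surv > 0) & (ks > 0)
    k_pos, s_pos = ks[keep], surv[keep]
    if k_pos.size < 3:
        raise ValueError("too few distinct positive degrees to fit a tail")
    y = np.log(s_pos)

    def _r2(x):
        slope, icpt = np.polyfit(x, y, 1)
        resid = y - (slope * x + icpt)
        ss_tot = ((y - y.mean()) ** 2).sum()
        return 1 - (resid**2).sum() / ss_tot, slope

    r2_exp, b_exp = _r2(k_pos.astype(float))
    r2_pow, b_pow = _r2(np.log(k_pos.astype(float)))
    if abs(r2_exp - r2_pow) < 0.01:
        cls = "indeterminate"
    elif r2_exp > r2_pow:
        cls = "exponential"
    else:
        cls = "power-law"
    return {
        "classification": cls,
        "r2_exponential": r2_exp,
        "r2_power_law": r2_pow,
        "slope_exponential": b_exp,
        "slope_power_law": b_pow,
    }


def random_walk_betweenness(graph: nx.Graph) -> dict:
    """Exact random-walk (current-flow) betweenness centrality per node.

    Deterministic electrical-current formulation; requires a connected
    graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph):
        raise ValueError("current-flow betweenness requires a connected graph")
    if graph.number_of_nodes() < 3:
        return {v: 0.0 for v in graph.nodes}
    return nx.current_flow_betweenness_centrality(graph, normalized=True)


def mc_walk_betweenness(graph: nx.Graph, walks: int, seed, pairs=None) -> dict:
    """Monte-Carlo random-walk betweenness estimate.

    For each of ``walks`` draws, a source and a distinct target are chosen
    uniformly (or from ``pairs``, if given) and a simple random walk from
    the source runs until absorbed at the target; every node records how
    often the walk visited it, walk endpoints excluded.  The estimate is
    the per-node mean visit count per walk.  Converges (in rank) to the
    exact current-flow measure.
    """
    if walks < 1:
        raise ValueError("need walks >= 1")
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least two nodes")
    if not nx.is_connected(graph):
        raise ValueError("random walks require a connected graph")
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    nbrs = [np.sort([idx[u] for u in graph.neighbors(v)]) for v in nodes]
    pair_pool = None
    if pairs is not None:
        pair_pool = [(idx[u], idx[v]) for u, v in pairs]
        if any(u == v for u, v in pair_pool):
            raise ValueError("source and target must differ")
    visits = np.zeros(len(nodes))
    for _ in range(walks):
        if pair_pool is None:
            s, t = rng.choice(len(nodes), size=2, replace=False)
        else:
            s, t = pair_pool[rng.integers(len(pair_pool))]
        v = s
        while v != t:
            v = nbrs[v][rng.integers(len(nbrs[v]))]
            if v != t and v != s:
                visits[v] += 1
    visits /= walks
    return {nodes[i]: visits[i] for i in range(len(nodes))}


def betweenness_rank_agreement(graph: nx.Graph, walks: int, seed) -> float:
    """Spearman rank correlation between the MC estimate and the exact measure."""
    exact = random_walk_betweenness(graph)
    mc = mc_walk_betweenness(graph, walks, seed)
    nodes = list(graph.nodes)
    rho, _ = spearmanr([exact[v] for v in nodes], [mc[v] for v in nodes])
    return float(rho)
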