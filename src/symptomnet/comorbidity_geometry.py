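"""Inter-disorder distances in the symptom graph versus empirical comorbidity.

The distance between disorders A and B is the expected number of edges to
travel between a randomly chosen symptom of A and a randomly chosen
symptom of B — the mean geodesic length over all ordered symptom pairs
(s in A, t in B), where a symptom shared by both disorders contributes
distance-0 self pairs.  If symptom activation spreads along the graph and
all connections are positive, nearer disorders should be more comorbid:
the distance–comorbidity correlation should be negative, and the
comorbidity matrix should form a positive manifold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from symptomnet.incidence_model import IncidenceTable
from symptomnet.network_stats import all_pairs_shortest_paths

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisorderDistanceMatrix:
    """Average inter-symptom geodesic length per disorder pair.

    ``distances`` is a symmetric labeled DataFrame (NaN where a pair is
    unreachable); ``shares_symptoms`` flags pairs with at least one common
    symptom.
    """

    disorders: tuple
    distances: pd.DataFrame
    shares_symptoms: pd.DataFrame


@dataclass(frozen=True)
class ComorbidityMatrix:
    """Symmetric disorder × disorder association matrix, values in [-1, 1]."""

    disorders: tuple
    values: pd.DataFrame

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("comorbidity matrix must be symmetric")
        off = v[~np.eye(len(v), dtype=bool)]
        if np.nanmax(np.abs(off)) > 1 + 1e-9:
            raise ValueError("comorbidity values must lie in [-1, 1]")

    @classmethod
    def from_csv(cls, path) -> "ComorbidityMatrix":
        df = pd.read_csv(path, index_col=0)
        df.columns = [str(c).strip() for c in df.columns]
        df.index = [str(i).strip() for i in df.index]
        return cls(disorders=tuple(df.index), values=df)


def disorder_distance_matrix(
    graph: nx.Graph, table: IncidenceTable, disorders=None
) -> DisorderDistanceMatrix:
    """Average shortest path length between every pair of disorders.

    Entry (A, B) is the mean of geodesic lengths over all ordered symptom
    pairs (s in A, t in B); shared symptoms contribute 0 through their
    self pairs.  Pairs whose symptoms span different components are NaN
    (flagged unreachable) and excluded downstream.
    """
    if disorders is None:
        disorders = list(table.disorders)
    missing = [d for d in disorders if d not in set(table.disorders)]
    if missing:
        raise KeyError(f"disorders absent from the incidence table: {missing}")
    nodes, lengths, _ = all_pairs_shortest_paths(graph)
    idx = {v: i for i, v in enumerate(nodes)}
    member_idx = {
        d: np.array(sorted(idx[s] for s in table.symptoms_of(d))) for d in disorders
    }
    k = len(disorders)
    dist = np.full((k, k), np.nan)
    share = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a, k):
            da, db = disorders[a], disorders[b]
            block = lengths[np.ix_(member_idx[da], member_idx[db])]
            if np.isnan(block).any():
                logger.info("disorders %s and %s are not mutually reachable", da, db)
                val = np.nan
            else:
                val = float(block.mean())
            dist[a, b] = dist[b, a] = val
            shared = bool(table.symptoms_of(da) & table.symptoms_of(db))
            share[a, b] = share[b, a] = shared
    labels = list(disorders)
    return DisorderDistanceMatrix(
        disorders=tuple(disorders),
        distances=pd.DataFrame(dist, index=labels, columns=labels),
        shares_symptoms=pd.DataFrame(share, index=labels, columns=labels),
    )


def pair_table(dist: DisorderDistanceMatrix, comorb: ComorbidityMatrix) -> pd.DataFrame:
    """Tidy unordered-pair table joining distances with comorbidity.

    Columns: disorder_a, disorder_b, distance, comorbidity,
    shares_symptoms.  Restricted to disorders present in both inputs;
    unreachable pairs are dropped.
    """
    common = [d for d in dist.disorders if d in set(comorb.disorders)]
    if len(common) < 2:
        raise ValueError("fewer than two disorders shared between inputs")
    rows = []
    for a, b in combinations(common, 2):
        d = dist.distances.loc[a, b]
        if np.isnan(d):
            continue
        rows.append(
            {
                "disorder_a": a,
                "disorder_b": b,
                "distance": float(d),
                "comorbidity": float(comorb.values.loc[a, b]),
                "shares_symptoms": bool(dist.shares_symptoms.loc[a, b]),
            }
        )
    return pd.DataFrame(rows)


def distance_comorbidity_correlation(
    dist: DisorderDistanceMatrix,
    comorb: ComorbidityMatrix,
    subset: str = "all",
    method: str = "pearson",
) -> float:
    """Correlation between inter-disorder distance and comorbidity.

    ``subset="no-shared-symptoms"`` keeps only pairs of disorders with no
    common symptom, removing the trivial contribution of bridge overlap.
    """
    if subset not in ("all", "no-shared-symptoms"):
        raise ValueError("subset must be 'all' or 'no-shared-symptoms'")
    tab = pair_table(dist, comorb)
    if subset == "no-shared-symptoms":
        tab = tab[~tab["shares_symptoms"]]
    if len(tab) < 3:
        raise ValueError("need at least 3 usable disorder pairs")
    x, y = tab["distance"].to_numpy(), tab["comorbidity"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in distances or comorbidities")
    if method == "pearson":
        r, _ = pearsonr(x, y)
    elif method == "spearman":
        r, _ = spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r)


def positive_manifold_check(comorb: ComorbidityMatrix, tol: float = 0.0):
    """Check that all off-diagonal comorbidities are nonnegative.

    Entries below ``-tol`` count as violations (a small positive ``tol``
    absorbs sampling noise in simulated matrices).

    Returns
    -------
    (bool, list of (a, b, value))
        Whether the manifold is positive, and the offending pairs.
    """
    v = comorb.values
    bad = []
    for a, b in combinations(comorb.disorders, 2):
        val = float(v.loc[a, b])
        if val < -tol:
            bad.append((a, b, val))
    return (len(bad) == 0), bad
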