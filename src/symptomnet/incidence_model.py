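"""Symptom–disorder incidence tables and their projection to a symptom graph.

The incidence table is the bipartite structure underlying the whole
analysis: rows are symptoms, columns are disorders, and a membership
(s, d) records that symptom ``s`` is a diagnostic criterion for disorder
``d``.  Projecting onto the symptom side yields an undirected simple graph
in which two symptoms are adjacent whenever some disorder lists both — so
every disorder's symptom set induces a clique, and disorders sharing
"bridge" symptoms become connected through them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class IncidenceValidationError(ValueError):
    """The incidence table violates a structural invariant."""


class IncidenceParseError(ValueError):
    """The incidence file could not be parsed."""


@dataclass(frozen=True)
class IncidenceTable:
    """Bipartite symptom × disorder membership structure.

    Parameters
    ----------
    symptoms : tuple of str
        Ordered unique symptom identifiers.
    disorders : tuple of str
        Ordered unique disorder identifiers.
    membership : frozenset of (str, str)
        (symptom, disorder) pairs; each records that the symptom is a
        diagnostic criterion of the disorder.
    chapters : dict, optional
        Optional category/chapter label per disorder.
    """

    symptoms: tuple
    disorders: tuple
    membership: frozenset
    chapters: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        sym = set(self.symptoms)
        dis = set(self.disorders)
        if len(sym) != len(self.symptoms):
            raise IncidenceValidationError("duplicate symptom identifiers")
        if len(dis) != len(self.disorders):
            raise IncidenceValidationError("duplicate disorder identifiers")
        for s, d in self.membership:
            if s not in sym:
                raise IncidenceValidationError(f"membership references undeclared symptom {s!r}")
            if d not in dis:
                raise IncidenceValidationError(f"membership references undeclared disorder {d!r}")
        covered_d = {d for _, d in self.membership}
        empty = dis - covered_d
        if empty:
            raise IncidenceValidationError(
                f"disorders with no symptoms: {sorted(empty)}"
            )
        covered_s = {s for s, _ in self.membership}
        orphan = sym - covered_s
        if orphan:
            raise IncidenceValidationError(
                f"symptoms belonging to no disorder: {sorted(orphan)}"
            )

    @property
    def n_symptoms(self) -> int:
        return len(self.symptoms)

    @property
    def n_disorders(self) -> int:
        return len(self.disorders)

    @property
    def n_memberships(self) -> int:
        return len(self.membership)

    def symptoms_of(self, disorder: str) -> frozenset:
        if disorder not in set(self.disorders):
            raise KeyError(disorder)
        return frozenset(s for s, d in self.membership if d == disorder)

    def disorders_of(self, symptom: str) -> frozenset:
        return frozenset(d for s, d in self.membership if s == symptom)

    def to_matrix(self) -> pd.DataFrame:
        """0/1 membership matrix (symptoms × disorders)."""
        mat = pd.DataFrame(0, index=list(self.symptoms), columns=list(self.disorders), dtype=int)
        for s, d in self.membership:
            mat.loc[s, d] = 1
        return mat

    @classmethod
    def from_pairs(cls, pairs, chapters=None) -> "IncidenceTable":
        """Build from an iterable of (symptom, disorder) pairs.

        Identifier order follows first appearance; duplicates collapse.
        """
        pairs = [(str(s).strip(), str(d).strip()) for s, d in pairs]
        seen = set()
        uniq = []
        for p in pairs:
            if p not in seen:
                seen.add(p)
                uniq.append(p)
        if len(uniq) < len(pairs):
            logger.warning("collapsed %d duplicate membership rows", len(pairs) - len(uniq))
        symptoms, disorders = [], []
        for s, d in uniq:
            if s not in symptoms:
                symptoms.append(s)
            if d not in disorders:
                disorders.append(d)
        return cls(
            symptoms=tuple(symptoms),
            disorders=tuple(disorders),
            membership=frozenset(uniq),
            chapters=dict(chapters or {}),
        )

    @classmethod
    def from_matrix(cls, mat: pd.DataFrame, chapters=None) -> "IncidenceTable":
        """Build from a labeled 0/1 matrix (rows = symptoms, cols = disorders)."""
        vals = set(pd.unique(mat.values.ravel()))
        if not vals <= {0, 1}:
            raise IncidenceParseError(f"matrix entries must be 0/1, found {sorted(vals - {0, 1})}")
        empty_cols = [str(d) for d in mat.columns if mat[d].sum() == 0]
        if empty_cols:
            raise IncidenceValidationError(f"disorders with no symptoms: {empty_cols}")
        empty_rows = [str(s) for s in mat.index if mat.loc[s].sum() == 0]
        if empty_rows:
            raise IncidenceValidationError(
                f"symptoms belonging to no disorder: {empty_rows}"
            )
        pairs = [
            (str(s).strip(), str(d).strip())
            for s in mat.index
            for d in mat.columns
            if mat.loc[s, d] == 1
        ]
        return cls.from_pairs(pairs, chapters=chapters)


def read_incidence(path, dialect: str = "long") -> IncidenceTable:
    """Read an incidence table from a plain-text file.

    Parameters
    ----------
    path : str or Path
        File to read.
    dialect : {"long", "matrix"}
        ``"long"``: two-column (symptom, disorder) rows with a header,
        tab- or comma-separated.  ``"matrix"``: labeled 0/1 matrix CSV with
        symptoms as rows and disorders as columns.

    Returns
    -------
    IncidenceTable
        Validated table; duplicate long-form rows are collapsed with a
        logged warning.
    """
    if dialect == "long":
        try:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        except Exception as exc:  # noqa: BLE001 - surface parse context
            raise IncidenceParseError(f"could not parse {path}: {exc}") from exc
        if df.shape[1] < 2:
            raise IncidenceParseError(
                f"{path}: long-form input needs two columns (symptom, disorder)"
            )
        bad = df[df.iloc[:, 0].isna() | df.iloc[:, 1].isna()]
        if len(bad):
            # +2: header line plus 1-based line numbering
            raise IncidenceParseError(
                f"{path}: malformed row at line {bad.index[0] + 2}"
            )
        return IncidenceTable.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if dialect == "matrix":
        try:
            mat = pd.read_csv(path, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise IncidenceParseError(f"could not parse {path}: {exc}") from exc
        return IncidenceTable.from_matrix(mat)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'matrix'")


def project_to_symptom_graph(table: IncidenceTable) -> nx.Graph:
    """Project the bipartite incidence onto the symptom space.

    Two symptoms are joined by an edge iff at least one disorder lists
    both as criteria, so each disorder's symptom set induces a clique.
    The graph is simple: co-occurrence in several disorders still yields
    a single edge, with the co-occurrence count kept as edge attribute
    ``weight`` (unused by the statistics).

    Node attribute ``disorders`` carries the back-map from each symptom to
    the disorders it belongs to.
    """
    g = nx.Graph()
    g.add_nodes_from(table.symptoms)
    for d in table.disorders:
        members = sorted(table.symptoms_of(d))
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                if g.has_edge(u, v):
                    g[u][v]["weight"] += 1
                else:
                    g.add_edge(u, v, weight=1)
    for s in table.symptoms:
        g.nodes[s]["disorders"] = sorted(table.disorders_of(s))
    return g


def write_graph(graph: nx.Graph, path, format: str = "edge-list") -> None:
    """Write a symptom graph as a plain edge list or GraphML.

    The round-trip property holds: reading the written file back yields a
    graph with identical node and edge sets.
    """
    if format == "edge-list":
        with open(path, "w") as fh:
            for u in graph.nodes:
                if graph.degree(u) == 0:
                    fh.write(f"{u}\n")
            for u, v in graph.edges:
                fh.write(f"{u}\t{v}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from(graph.edges)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'edge-list' or 'graphml'")


def read_graph(path, format: str = "edge-list") -> nx.Graph:
    """Read a graph written by :func:`write_graph`."""
    if format == "edge-list":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) == 2:
                    g.add_edge(parts[0], parts[1])
        return g
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown format {format!r}; expected 'edge-list' or 'graphml'")
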