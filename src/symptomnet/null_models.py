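"""Degree-preserving bipartite permutation null model.

Symptoms are reassorted randomly over disorders while every symptom keeps
its number of disorder memberships and every disorder keeps its symptom
count — i.e. the bipartite incidence matrix is resampled with fixed row
and column margins.  Sampling uses a checkerboard swap chain (2×2
submatrix exchanges), the standard approach for fixed-margin binary
matrices.  Comparing the observed small-world index with this ensemble
asks whether the observed clustering exceeds what identical symptom and
disorder degrees alone would produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from symptomnet.incidence_model import IncidenceTable, project_to_symptom_graph
from symptomnet.network_stats import giant_component, small_world_index, summarize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationEnsemble:
    """Per-replicate statistics of the degree-preserving null."""

    reps: int
    swi: np.ndarray
    c: np.ndarray
    l: np.ndarray
    density: np.ndarray
    seed: object
    swaps: int


def randomize_bipartite(table: IncidenceTable, seed) -> IncidenceTable:
    """Resample an incidence table uniformly with fixed margins.

    Row sums (symptom bipartite degrees) and column sums (disorder sizes)
    are preserved exactly.  Mixing uses repeated checkerboard swaps: pick
    two memberships (s1,d1), (s2,d2) with s1 != s2, d1 != d2 and exchange
    them for (s1,d2), (s2,d1) when both are absent.  The chain runs until
    at least 10× the membership count of swaps are accepted (with an
    attempt cap for degenerate margins).
    """
    rng = np.random.default_rng(seed)
    pairs = sorted(table.membership)
    sym_i = {s: i for i, s in enumerate(table.symptoms)}
    dis_i = {d: j for j, d in enumerate(table.disorders)}
    edges = [(sym_i[s], dis_i[d]) for s, d in pairs]
    present = set(edges)
    n_e = len(edges)
    target = 10 * n_e
    accepted = 0
    attempts = 0
    max_attempts = 400 * n_e
    while accepted < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(n_e), rng.integers(n_e)
        (s1, d1), (s2, d2) = edges[i], edges[j]
        if s1 == s2 or d1 == d2:
            continue
        if (s1, d2) in present or (s2, d1) in present:
            continue
        present.discard((s1, d1))
        present.discard((s2, d2))
        present.add((s1, d2))
        present.add((s2, d1))
        edges[i] = (s1, d2)
        edges[j] = (s2, d1)
        accepted += 1
    if accepted == 0:
        logger.info("margins admit no checkerboard swap; returning input unchanged")
        return table
    if accepted < target:
        logger.info(
            "swap chain stopped after %d accepted swaps (target %d)", accepted, target
        )
    new_pairs = [(table.symptoms[s], table.disorders[d]) for s, d in present]
    return IncidenceTable(
        symptoms=table.symptoms,
        disorders=table.disorders,
        membership=frozenset(new_pairs),
        chapters=table.chapters,
    )


def permutation_swi_distribution(
    table: IncidenceTable, reps: int, seed, restrict: str = "giant"
):
    """SWI ensemble under the degree-preserving permutation null.

    Each replicate reassorts the incidence with fixed margins, projects it
    to the symptom graph, restricts to the replicate's own giant component
    (``restrict="giant"``, default) or analyses the full graph if it is
    connected (``restrict="full"``), and records SWI, C, L and density.

    Returns
    -------
    (PermutationEnsemble, float, float)
        The ensemble, the observed SWI of the input's giant component, and
        the percentile (0–100) of the observed SWI in the ensemble.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    if restrict not in ("giant", "full"):
        raise ValueError("restrict must be 'giant' or 'full'")
    rng = np.random.default_rng(seed)

    def _swi_of(tbl):
        g = project_to_symptom_graph(tbl)
        if restrict == "giant":
            g, _ = giant_component(g)
        summ = summarize(g)
        res = small_world_index(summ.transitivity, summ.avg_path_length, summ.n, summ.m)
        return res.swi, summ.transitivity, summ.avg_path_length, summ.density

    obs_swi, _, _, _ = _swi_of(table)
    swi = np.empty(reps)
    c = np.empty(reps)
    l = np.empty(reps)
    dens = np.empty(reps)
    for r in range(reps):
        rt = randomize_bipartite(table, int(rng.integers(2**31)))
        swi[r], c[r], l[r], dens[r] = _swi_of(rt)
    pct = 100.0 * (swi < obs_swi).mean()
    ens = PermutationEnsemble(
        reps=reps, swi=swi, c=c, l=l, density=dens, seed=seed, swaps=10 * table.n_memberships
    )
    return ens, obs_swi, pct
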