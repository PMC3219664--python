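"""Generators for synthetic study inputs.

Three external inputs feed the analyses: a symptom–disorder incidence
table, per-symptom activation parameters (b_i, c_i), and an inter-disorder
comorbidity matrix.  The generators here produce structured stand-ins for
all three, so every stage of the pipeline closes end-to-end on data whose
ground truth is known:

* :func:`mde_gad_fixture` — the exact 14-symptom MDE/GAD network (five
  core symptoms per disorder plus four shared bridge symptoms) together
  with the DSM-IV-style diagnosis rules.
* :func:`generate_incidence` — chain/ring/disjoint families of disorders
  with controllable bridge-symptom overlap.
* :func:`generate_params` / :func:`calibrate` — symptom parameters drawn
  from a configurable distribution, with thresholds c_i tuned by bisection
  so that simulated marginal activation rates hit per-symptom targets.
* :func:`generate_comorbidity_scenario` — a comorbidity matrix that truly
  arises from the graph, by simulating a population and cross-classifying
  diagnoses (phi coefficients as the tetrachoric stand-in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from symptomnet.comorbidity_geometry import ComorbidityMatrix
from symptomnet.diagnosis_stats import DiagnosisRule, diagnose
from symptomnet.dynamics import DynamicsSpec, simulate_population
from symptomnet.incidence_model import IncidenceTable, project_to_symptom_graph
from symptomnet.network_stats import ordered_subgraph

logger = logging.getLogger(__name__)

#: global floor/ceiling parameter of the activation dynamics
DEFAULT_A = 0.22

MDE_CORES = ("mDep", "mInt", "mWei", "mRep", "mSui")
BRIDGES = ("bSle", "bFat", "bCon", "bMot")
GAD_CORES = ("gAnx", "gEve", "gCtr", "gMus", "gIrr")

#: per-symptom target marginal daily activation rates for the calibrated
#: MDE/GAD scenario.  GAD symptoms run more prevalent than MDE symptoms,
#: matching the empirical ordering that the chronicity criterion then
#: inverts at the disorder level (GAD diagnoses are rarer than MDE despite
#: commoner symptoms).
DEFAULT_TARGET_RATES = {
    "mDep": 0.105, "mInt": 0.105, "mWei": 0.100, "mRep": 0.100, "mSui": 0.100,
    "bSle": 0.105, "bFat": 0.105, "bCon": 0.105, "bMot": 0.105,
    "gAnx": 0.148, "gEve": 0.148, "gCtr": 0.148, "gMus": 0.148, "gIrr": 0.148,
}

#: per-symptom sensitivities for the calibrated MDE/GAD scenario.  The
#: regime is deliberately asymmetric: GAD core symptoms are strongly
#: self-reinforcing (long, chronic activation states that can satisfy a
#: six-month most-days criterion), the non-core MDE symptoms moderately
#: so (two-to-four-week episodes), the two designated MDE core symptoms
#: and the bridge symptoms only weakly reactive.  Weak bridges limit how
#: easily an episode in one disorder ignites the other, keeping the
#: comorbidity odds ratio finite rather than letting every cascade go
#: network-wide.
DEFAULT_SENSITIVITIES = {
    "mDep": 0.83, "mInt": 0.83, "mWei": 1.03, "mRep": 1.03, "mSui": 1.03,
    "bSle": 0.80, "bFat": 0.80, "bCon": 0.80, "bMot": 0.80,
    "gAnx": 1.32, "gEve": 1.32, "gCtr": 1.32, "gMus": 1.32, "gIrr": 1.32,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of a synthetic incidence/dynamics scenario.

    ``bridge_overlap`` is the number of symptoms shared by each adjacent
    disorder pair in chain/ring topologies (0 gives disjoint cliques).
    ``b_range`` bounds the uniform draw of symptom sensitivities.
    """

    n_disorders: int = 6
    symptoms_per_disorder: int = 6
    bridge_overlap: int = 2
    topology: str = "chain"
    disorders_per_family: int = 3
    family_core: int = 4
    a: float = DEFAULT_A
    b_range: tuple = (0.9, 1.5)
    target_rate_range: tuple = (0.07, 0.11)
    n_persons: int = 9282
    days: int = 365
    seed: int = 0

    def __post_init__(self):
        if self.n_disorders < 1 or self.symptoms_per_disorder < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.bridge_overlap < self.symptoms_per_disorder:
            raise ValueError("bridge overlap must be smaller than disorder size")
        if self.topology not in ("chain", "ring", "disjoint", "families"):
            raise ValueError(
                "topology must be 'chain', 'ring', 'disjoint' or 'families'"
            )
        if self.topology == "families":
            if not 0 < self.family_core < self.symptoms_per_disorder:
                raise ValueError("family core must be smaller than disorder size")
            if self.bridge_overlap > self.family_core:
                raise ValueError("family chaining cannot exceed the family core")


def mde_gad_fixture():
    """The 14-symptom MDE/GAD network with its diagnosis rules.

    Two nine-symptom disorders share the four bridge symptoms; core MDE
    and core GAD symptoms are never directly connected, so comorbidity can
    only arise through the bridges.  The projection has 66 edges.

    Returns
    -------
    (IncidenceTable, (DiagnosisRule, DiagnosisRule), dict)
        Incidence, (MDE rule, GAD rule), and a dynamics skeleton with
        keys ``a`` (0.22), ``sensitivities`` and ``target_rates`` for
        calibration.
    """
    mde = MDE_CORES + BRIDGES
    gad = GAD_CORES + BRIDGES
    pairs = [(s, "MDE") for s in mde] + [(s, "GAD") for s in gad]
    table = IncidenceTable.from_pairs(pairs)
    mde_rule = DiagnosisRule(
        disorder="MDE",
        symptoms=mde,
        cores=("mDep", "mInt"),
        min_count=5,
        window=14,
        criterion="every-day",
    )
    gad_rule = DiagnosisRule(
        disorder="GAD",
        symptoms=gad,
        cores=("gAnx", "gEve", "gCtr"),
        window=182,
        criterion="most-days",
    )
    skeleton = {
        "a": DEFAULT_A,
        "target_rates": dict(DEFAULT_TARGET_RATES),
        "sensitivities": dict(DEFAULT_SENSITIVITIES),
    }
    return table, (mde_rule, gad_rule), skeleton


def generate_incidence(config: ScenarioConfig) -> IncidenceTable:
    """Structured synthetic incidence table.

    ``chain``: disorder i shares ``bridge_overlap`` symptoms with disorder
    i+1; ``ring`` additionally joins the last disorder back to the first;
    ``disjoint`` ignores the overlap and yields separate cliques;
    ``families`` groups ``n_disorders`` families of
    ``disorders_per_family`` disorders each sharing a ``family_core``
    symptom group (disorders re-using symptom groups, the structural
    feature a degree-preserving reassortment destroys), with adjacent
    families chained through ``bridge_overlap`` shared core symptoms.
    Deterministic under ``config.seed`` (labels are structural, so the
    seed only matters for future randomized topologies).
    """
    k, s, ov = config.n_disorders, config.symptoms_per_disorder, config.bridge_overlap
    topology = config.topology
    if topology == "families":
        return _generate_family_incidence(config)
    if topology == "disjoint":
        ov = 0
    if topology == "ring" and k == 2 and 2 * ov >= s:
        raise ValueError("ring with two disorders needs 2*overlap < disorder size")
    if topology == "ring" and k > 2 and 2 * ov > s:
        raise ValueError("infeasible overlap: adjacent bridges exceed disorder size")
    pairs = []
    next_id = 0

    def fresh(n):
        nonlocal next_id
        out = [f"s{next_id + i:03d}" for i in range(n)]
        next_id += n
        return out

    shared_next = []  # symptoms shared with the following disorder
    first_shared = None
    for i in range(k):
        d = f"D{i + 1:02d}"
        members = list(shared_next)
        is_last = i == k - 1
        if topology == "ring" and is_last and k > 1:
            members += first_shared
        n_new = s - len(members)
        if ov > 0 and not (is_last and topology != "ring"):
            shared_next = fresh(ov)
            members += shared_next
            n_new -= ov
            if i == 0 and topology == "ring" and k > 1:
                # reserve a distinct bridge set for the ring-closing pair
                first_shared = fresh(ov)
                members += first_shared
                n_new -= ov
        if n_new < 0:
            raise ValueError("infeasible overlap for disorder size")
        members += fresh(n_new)
        pairs += [(m, d) for m in members]
    return IncidenceTable.from_pairs(pairs)


def _generate_family_incidence(config: ScenarioConfig) -> IncidenceTable:
    """Families of disorders sharing symptom-group cores, chained."""
    pairs = []
    next_id = 0

    def fresh(n):
        nonlocal next_id
        out = [f"s{next_id + i:03d}" for i in range(n)]
        next_id += n
        return out

    prev_core = None
    for f in range(config.n_disorders):
        core = fresh(config.family_core)
        if prev_core is not None and config.bridge_overlap > 0:
            core[: config.bridge_overlap] = prev_core[-config.bridge_overlap:]
        extras_per = config.symptoms_per_disorder - config.family_core
        for d in range(config.disorders_per_family):
            members = core + fresh(extras_per)
            pairs += [(m, f"F{f + 1:02d}D{d + 1}") for m in members]
        prev_core = core
    return IncidenceTable.from_pairs(pairs)


def generate_params(table: IncidenceTable, config: ScenarioConfig, seed=None) -> pd.DataFrame:
    """Draw per-symptom (b, c) and marginal-rate targets.

    Sensitivities b are uniform on ``config.b_range``; initial thresholds
    c start at 2b (so a symptom needs a couple of active neighbours to
    pass its threshold) and are meant to be refined by :func:`calibrate`.
    Target rates are uniform on ``config.target_rate_range``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    symptoms = list(table.symptoms)
    b = rng.uniform(*config.b_range, size=len(symptoms))
    targets = rng.uniform(*config.target_rate_range, size=len(symptoms))
    return pd.DataFrame({"b": b, "c": 2 * b, "target_rate": targets}, index=symptoms)


def calibrate(
    graph: nx.Graph,
    a: float,
    b: dict,
    target_rates: dict,
    seed,
    n_persons: int = 2000,
    T: int = 100,
    tol: float = 0.02,
    max_iter: int = 18,
    c_bounds: tuple = (-8.0, 20.0),
) -> pd.DataFrame:
    """Tune thresholds c_i so simulated marginal rates hit their targets.

    Joint per-symptom bisection on c_i: every iteration simulates a
    population under the current threshold vector (common random numbers
    across iterations) and moves each symptom's bracket according to
    whether its mean activation over the second half of the run exceeds
    its target.  Rates are monotone decreasing in the symptom's own c, and
    cross-symptom coupling is absorbed by the joint iteration.

    Targets below the spontaneous floor a² are unreachable; the bisection
    then fails the tolerance check and raises with diagnostics.

    Returns a DataFrame indexed by symptom with columns ``b``, ``c`` and
    ``achieved_rate``.
    """
    symptoms = list(graph.nodes)
    missing = [s for s in symptoms if s not in b or s not in target_rates]
    if missing:
        raise KeyError(f"missing b or target for symptoms: {missing}")
    tvec = np.array([target_rates[s] for s in symptoms])
    if np.any((tvec <= 0) | (tvec >= 1)):
        raise ValueError("target rates must lie in (0, 1)")
    lo = np.full(len(symptoms), c_bounds[0])
    hi = np.full(len(symptoms), c_bounds[1])
    burn = T // 2
    achieved = np.full(len(symptoms), np.nan)
    mid = (lo + hi) / 2
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        spec = DynamicsSpec(
            graph=graph, a=a, b=dict(b), c=dict(zip(symptoms, mid))
        )
        panel = simulate_population(spec, n_persons, T, seed)
        achieved = panel.data[:, :, burn:].mean(axis=(0, 2))
        too_high = achieved > tvec
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
    err = np.abs(achieved - tvec)
    if err.max() > tol:
        worst = int(err.argmax())
        raise RuntimeError(
            f"calibration did not converge: symptom {symptoms[worst]!r} achieved "
            f"rate {achieved[worst]:.4f} vs target {tvec[worst]:.4f} "
            f"(tol {tol}); note the spontaneous floor is a² = {a * a:.4f}"
        )
    return pd.DataFrame(
        {"b": [b[s] for s in symptoms], "c": mid, "achieved_rate": achieved},
        index=symptoms,
    )


def shuffle_params(params: pd.DataFrame, seed) -> pd.DataFrame:
    """Permute intact (b, c) pairs across symptoms.

    The multiset of pairs is preserved; only their assignment to symptoms
    changes.  This is the "random model" control: right parameters,
    wrong symptoms.
    """
    if len(params) < 2:
        raise ValueError("need at least two symptoms to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(params))
    out = params.iloc[perm].copy()
    out.index = params.index
    return out


def calibrated_mde_gad_spec(seed, n_persons: int = 2000, T: int = 100) -> DynamicsSpec:
    """Fixture network with calibrated parameters, ready to simulate.

    Sensitivities are :data:`DEFAULT_SENSITIVITIES`; thresholds are
    calibrated to :data:`DEFAULT_TARGET_RATES` (``seed`` drives the
    calibration simulations).
    """
    table, _, skeleton = mde_gad_fixture()
    graph = project_to_symptom_graph(table)
    rng = np.random.default_rng(seed)
    fitted = calibrate(
        graph, skeleton["a"], dict(DEFAULT_SENSITIVITIES), skeleton["target_rates"],
        seed=int(rng.integers(2**31)), n_persons=n_persons, T=T, tol=0.03,
    )
    return DynamicsSpec(
        graph=graph, a=skeleton["a"], b=fitted["b"].to_dict(), c=fitted["c"].to_dict()
    )


#: sensitivity assignment for the parameter-recovery scenario: each
#: symptom group spans the b range, so recovering the sensitivity ranking
#: from cross-sectional data is well-posed (distinct values, no
#: group/sensitivity confounding).
RECOVERY_SENSITIVITIES = {
    "mDep": 0.40, "mInt": 0.60, "mWei": 0.80, "mRep": 1.00, "mSui": 1.20,
    "bSle": 0.45, "bFat": 0.75, "bCon": 1.05, "bMot": 1.35,
    "gAnx": 0.50, "gEve": 0.70, "gCtr": 0.90, "gMus": 1.10, "gIrr": 1.30,
}


def recovery_spec(seed, target_rate: float = 0.10) -> DynamicsSpec:
    """Fixture network parameterised for parameter-recovery experiments.

    Sensitivities follow :data:`RECOVERY_SENSITIVITIES`; thresholds are
    calibrated so every symptom runs at the same marginal rate, leaving
    the sensitivity ranking as the only structure to recover.
    """
    table, _, skeleton = mde_gad_fixture()
    graph = project_to_symptom_graph(table)
    fitted = calibrate(
        graph, skeleton["a"], dict(RECOVERY_SENSITIVITIES),
        {s: target_rate for s in table.symptoms}, seed=seed, tol=0.03,
    )
    return DynamicsSpec(
        graph=graph, a=skeleton["a"], b=fitted["b"].to_dict(), c=fitted["c"].to_dict()
    )


def generic_majority_rule(disorder: str, symptoms, window: int = 7) -> DiagnosisRule:
    """Majority rule: > half the symptoms active on ``window`` consecutive days."""
    symptoms = tuple(symptoms)
    return DiagnosisRule(
        disorder=disorder,
        symptoms=symptoms,
        min_count=len(symptoms) // 2 + 1,
        window=window,
        criterion="every-day",
    )


def generate_comorbidity_scenario(
    config: ScenarioConfig,
    n_persons: int | None = None,
    T: int | None = None,
    window: int = 7,
):
    """Incidence table plus a comorbidity matrix that arises from the graph.

    Simulates a population on the projected graph with calibrated
    parameters, diagnoses every disorder by a generic majority rule, and
    returns the pairwise phi coefficients of the diagnoses as the
    comorbidity matrix (the synthetic proxy for tetrachoric correlations).

    Raises if any disorder's prevalence is degenerate (0 or 1).
    """
    if config.n_disorders < 4:
        raise ValueError("need at least 4 disorders for a comorbidity scenario")
    n_persons = config.n_persons if n_persons is None else n_persons
    T = config.days if T is None else T
    table = generate_incidence(config)
    graph = project_to_symptom_graph(table)
    params = generate_params(table, config)
    rng = np.random.default_rng(config.seed)
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    fitted = []
    for comp in comps:
        sub = ordered_subgraph(graph, sorted(comp))
        fitted.append(
            calibrate(
                sub, config.a,
                params["b"].to_dict(),
                params["target_rate"].to_dict(),
                seed=int(rng.integers(2**31)),
            )
        )
    fitted = pd.concat(fitted).loc[list(table.symptoms)]
    spec = DynamicsSpec(
        graph=graph, a=config.a, b=fitted["b"].to_dict(), c=fitted["c"].to_dict()
    )
    panel = simulate_population(spec, n_persons, T, int(rng.integers(2**31)))
    diagnoses = {}
    for d in table.disorders:
        rule = generic_majority_rule(d, sorted(table.symptoms_of(d)), window=window)
        diag = diagnose(panel, rule)
        prev = diag.mean()
        if prev in (0.0, 1.0):
            raise RuntimeError(
                f"degenerate prevalence {prev:.0f} for {d}; recalibrate with "
                f"different target rates or a longer simulation"
            )
        diagnoses[d] = diag.astype(float)
    dmat = pd.DataFrame(diagnoses)
    phi = dmat.corr().to_numpy()
    np.fill_diagonal(phi, 1.0)
    values = pd.DataFrame(phi, index=dmat.columns, columns=dmat.columns)
    return table, ComorbidityMatrix(disorders=tuple(dmat.columns), values=values)
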