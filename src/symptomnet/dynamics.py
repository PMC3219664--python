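"""Stochastic symptom-activation dynamics on a symptom graph.

Each symptom i is a binary node updated synchronously in discrete time.
Given A = number of neighbours of i active at t-1, symptom i is active at
t with probability

    p = a + (1 - a) * (sigma(b_i * A - c_i) - a),

sigma the standard logistic.  ``a`` in (0,1) is the single global
parameter: with no active neighbours and a high threshold the activation
floor is a² (spontaneous onset), and with saturated input the probability
tops out at a + (1-a)², i.e. a symptom spontaneously deactivates with
probability a(1-a) even under full neighbour support.  ``b_i`` (>= 0) is
the symptom's sensitivity per active neighbour and ``c_i`` its threshold
on the linear predictor scale.

The update has no self-term: a symptom's own previous state matters only
through its neighbours, and "turning off" is simply failure to be on at
t.  Parameters (b_i, c_i) are estimated from cross-sectional data by
per-symptom logistic regression of endorsement on the number of other
symptoms of the disorder endorsed by the same person.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

logger = logging.getLogger(__name__)

#: documented cap for |b| and |c| when a logistic fit separates perfectly
SEPARATION_CAP = 10.0

#: refuse population simulations above this many panel cells
DEFAULT_CELL_CAP = 2_000_000_000


@dataclass(frozen=True)
class DynamicsSpec:
    """Network plus activation parameters defining the stochastic update.

    Attributes
    ----------
    graph : networkx.Graph
        Symptom graph (any undirected simple graph).
    a : float
        Global floor/ceiling parameter, in (0, 1).
    b : dict
        Per-symptom sensitivity (>= 0) per active neighbour.
    c : dict
        Per-symptom threshold (dimensionless, linear-predictor scale).
    """

    graph: nx.Graph
    a: float
    b: dict
    c: dict
    _order: tuple = field(init=False, compare=False, repr=False, default=())

    def __post_init__(self):
        if not 0 < self.a < 1:
            raise ValueError(f"a must lie in (0, 1), got {self.a}")
        nodes = tuple(self.graph.nodes)
        for v in nodes:
            if v not in self.b or v not in self.c:
                raise ValueError(f"symptom {v!r} is missing (b, c) parameters")
            if self.b[v] < 0:
                raise ValueError(f"b[{v!r}] must be nonnegative, got {self.b[v]}")
        object.__setattr__(self, "_order", nodes)

    @property
    def symptoms(self) -> tuple:
        return self._order

    def arrays(self):
        """(adjacency uint8 matrix, b vector, c vector) in symptom order."""
        adj = nx.to_numpy_array(self.graph, nodelist=list(self._order), weight=None)
        b = np.array([self.b[v] for v in self._order], dtype=float)
        c = np.array([self.c[v] for v in self._order], dtype=float)
        return adj, b, c


@dataclass(frozen=True)
class SymptomPanel:
    """Binary activation history: persons × symptoms × days.

    ``data[p, i, t]`` is symptom ``symptoms[i]``'s state for person ``p``
    on day ``t`` (the initial all-off state at t=0 is not stored; day 0 is
    the first updated state).
    """

    data: np.ndarray
    symptoms: tuple
    seed: object

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("panel must be persons × symptoms × days")
        if self.data.shape[1] != len(self.symptoms):
            raise ValueError("symptom axis does not match symptom labels")
        if self.data.shape[2] < 1:
            raise ValueError("need at least one day")
        vals = np.unique(self.data)
        if not set(vals.tolist()) <= {0, 1}:
            raise ValueError("panel entries must be binary")

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_days(self) -> int:
        return self.data.shape[2]

    def day_slice(self, day: int = -1) -> pd.DataFrame:
        """Cross-sectional persons × symptoms table for one day."""
        return pd.DataFrame(self.data[:, :, day], columns=list(self.symptoms))


def activation_probability(a, b, c, active_neighbors):
    """Probability that a symptom is active at t given neighbour input.

    p = a + (1-a) * (sigma(b*A - c) - a); strictly inside
    (a², a + (1-a)²) and nondecreasing in ``active_neighbors`` for b >= 0.
    Accepts scalars or broadcastable arrays.
    """
    a = float(a)
    if not 0 < a < 1:
        raise ValueError(f"a must lie in (0, 1), got {a}")
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    A = np.asarray(active_neighbors, dtype=float)
    if np.any(A < 0):
        raise ValueError("active neighbour count must be nonnegative")
    p = a + (1 - a) * (expit(b * A - c) - a)
    return p if p.ndim else float(p)


def _person_uniforms(master_seed, person: int, T: int, n_symptoms: int) -> np.ndarray:
    """Counter-based per-person random stream: U(T, n_symptoms)."""
    rng = np.random.default_rng([int(master_seed), int(person)])
    return rng.random((T, n_symptoms))


def _evolve(adj, b, c, a, uniforms):
    """Run the synchronous update against pre-drawn uniforms.

    ``uniforms`` has shape (..., T, S); the result has the same shape with
    binary entries.  The initial state (all symptoms off) is not returned.
    """
    T, S = uniforms.shape[-2], uniforms.shape[-1]
    out = np.empty(uniforms.shape, dtype=np.uint8)
    state = np.zeros(uniforms.shape[:-2] + (S,), dtype=float)
    for t in range(T):
        A = state @ adj
        p = a + (1 - a) * (expit(b * A - c) - a)
        state = (uniforms[..., t, :] < p).astype(float)
        out[..., t, :] = state
    return out


def simulate_person(spec: DynamicsSpec, T: int, seed) -> np.ndarray:
    """Simulate one person's symptom history.

    Returns a (n_symptoms, T) binary array in ``spec.symptoms`` order.
    The state at t=0 is all-off; day 0 of the output is the first update.
    Synchronous: every symptom's day-t state is drawn independently from
    :func:`activation_probability` evaluated at the day-(t-1) neighbour
    counts.
    """
    if T < 1:
        raise ValueError("need T >= 1")
    adj, b, c = spec.arrays()
    uniforms = np.random.default_rng(seed).random((T, len(b)))
    return _evolve(adj, b, c, spec.a, uniforms).T


def simulate_population(
    spec: DynamicsSpec, n_persons: int, T: int, seed, cell_cap: int = DEFAULT_CELL_CAP
) -> SymptomPanel:
    """Simulate ``n_persons`` independent persons.

    Per-person random streams are split from the master seed by a counter
    (person index), so each person's history equals
    ``simulate_person(spec, T, seed=[seed, p])`` and results do not depend
    on scheduling.  Refuses panels larger than ``cell_cap`` cells.
    """
    if n_persons < 1:
        raise ValueError("need n_persons >= 1")
    if T < 1:
        raise ValueError("need T >= 1")
    S = len(spec.symptoms)
    if n_persons * T * S > cell_cap:
        raise ValueError(
            f"panel of {n_persons}×{S}×{T} = {n_persons * T * S} cells exceeds "
            f"the cap of {cell_cap}; lower n_persons/T or raise cell_cap"
        )
    adj, b, c = spec.arrays()
    uniforms = np.empty((n_persons, T, S))
    for p in range(n_persons):
        uniforms[p] = _person_uniforms(seed, p, T, S)
    hist = _evolve(adj, b, c, spec.a, uniforms)  # (P, T, S)
    return SymptomPanel(
        data=np.ascontiguousarray(hist.transpose(0, 2, 1)),
        symptoms=spec.symptoms,
        seed=seed,
    )


def _fit_symptom(y, x, cap=SEPARATION_CAP):
    """Logistic fit of endorsement on a count predictor.

    Returns (b, c, flagged): slope, location (negated intercept, so the
    linear predictor reads b*count - c) and whether separation forced the
    documented cap.
    """
    X = sm.add_constant(np.asarray(x, dtype=float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(np.asarray(y, dtype=float), X).fit(disp=0, maxiter=200)
        icpt, slope = res.params
        if np.isfinite(slope) and np.isfinite(icpt) and abs(slope) <= cap and abs(icpt) <= cap:
            return float(slope), float(-icpt), False
    except Exception:  # noqa: BLE001 - statsmodels raises several separation errors
        pass
    # perfect or quasi-separation: keep the direction, cap the magnitude
    corr = np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1]
    sign = 1.0 if (np.isnan(corr) or corr >= 0) else -1.0
    logger.warning("logistic fit separated; capping parameters at ±%.1f", cap)
    return sign * cap, sign * -cap, True


def estimate_symptom_params(
    slice_df: pd.DataFrame, disorder_sets: dict, include_self: bool = False
) -> pd.DataFrame:
    """Estimate per-symptom (b, c) from a cross-sectional binary table.

    For each disorder and each of its symptoms, symptom endorsement is
    logistically regressed on the number of the disorder's *other*
    symptoms the person endorses (``include_self=True`` uses the literal
    total count instead, which is degenerate at the boundary and off by
    construction).  b is the slope, c the location (negated intercept).
    Symptoms belonging to several disorders get the average of their
    disorder-specific fits.

    Parameters
    ----------
    slice_df : DataFrame
        Persons × symptoms 0/1 table (e.g. ``panel.day_slice()``).
    disorder_sets : dict
        Disorder id -> iterable of its symptom ids.

    Returns
    -------
    DataFrame indexed by symptom with columns ``b``, ``c``, ``flagged``.
    """
    if len(slice_df) < 30:
        raise ValueError("need at least 30 persons to estimate parameters")
    fits: dict = {}
    for disorder, symptoms in disorder_sets.items():
        symptoms = list(symptoms)
        missing = [s for s in symptoms if s not in slice_df.columns]
        if missing:
            raise KeyError(f"symptoms {missing} of {disorder!r} absent from the data")
        block = slice_df[symptoms].to_numpy(dtype=float)
        total = block.sum(axis=1)
        for j, s in enumerate(symptoms):
            y = block[:, j]
            if y.min() == y.max():
                raise ValueError(
                    f"symptom {s!r} is constant in the sample; cannot regress"
                )
            x = total if include_self else total - y
            fits.setdefault(s, []).append(_fit_symptom(y, x))
    rows = {}
    for s, fs in fits.items():
        bs = [f[0] for f in fs]
        cs = [f[1] for f in fs]
        rows[s] = {
            "b": float(np.mean(bs)),
            "c": float(np.mean(cs)),
            "flagged": any(f[2] for f in fs),
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        [s for s in slice_df.columns if s in rows]
    ]
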