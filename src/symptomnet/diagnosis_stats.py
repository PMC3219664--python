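"""Diagnosis rules on simulated symptom histories and population statistics.

Two window criteria are supported, mirroring how DSM-IV handles episodic
versus chronic disorders:

* ``every-day`` (MDE-style): some run of ``window`` consecutive days on
  each of which at least ``min_count`` of the disorder's symptoms are
  active and, if core symptoms are declared, at least one core is active.
* ``most-days`` (GAD-style): some window of ``window`` days in which each
  core symptom is active on a strict majority of days and on a strict
  majority of days a strict majority of the symptom set is active.

Population statistics are yearly prevalence per disorder, the odds ratio
of joint diagnosis (Haldane 0.5 continuity correction when a cell is
empty), and Cronbach's alpha over all symptoms at the final day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from symptomnet.dynamics import DynamicsSpec, SymptomPanel, simulate_population

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagnosisRule:
    """Operationalized diagnosis criterion for one disorder.

    ``symptom_majority`` and ``day_majority`` only apply to the
    ``most-days`` criterion; both are strict (>) thresholds.
    ``fixed_set`` (every-day only) requires the same ``min_count`` symptoms
    on every day of the qualifying run, instead of letting the identity
    vary day to day.  ``core_whole_window`` (every-day only) evaluates the
    core requirement once over the run instead of per day.
    """

    disorder: str
    symptoms: tuple
    cores: tuple = ()
    min_count: int = 1
    window: int = 1
    criterion: str = "every-day"
    symptom_majority: float = 0.5
    day_majority: float = 0.5
    fixed_set: bool = False
    core_whole_window: bool = False

    def __post_init__(self):
        if not set(self.cores) <= set(self.symptoms):
            raise ValueError("core symptoms must be a subset of the symptom set")
        if not 1 <= self.min_count <= len(self.symptoms):
            raise ValueError("min_count must lie in [1, |symptoms|]")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.criterion not in ("every-day", "most-days"):
            raise ValueError("criterion must be 'every-day' or 'most-days'")


@dataclass(frozen=True)
class PopulationStats:
    """Prevalence, comorbidity and internal-consistency bundle."""

    prevalence: dict
    odds_ratio: float
    alpha: float
    or_unstable: bool = False
    replicate: int = 0


@dataclass(frozen=True)
class PlausibleRanges:
    """Closed plausibility intervals per statistic.

    ``prevalence`` maps disorder id to (lo, hi); defaults follow broadly
    accepted yearly epidemiological values for MDE and GAD.
    """

    prevalence: dict = field(
        default_factory=lambda: {"MDE": (0.05, 0.15), "GAD": (0.01, 0.05)}
    )
    odds_ratio: tuple = (5.0, 15.0)
    alpha: tuple = (0.6, 1.0)

    def __post_init__(self):
        for lo, hi in [*self.prevalence.values(), self.odds_ratio, self.alpha]:
            if not lo < hi:
                raise ValueError("each plausible range needs lower < upper")


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window sums of length w along the last axis."""
    cs = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    return cs[..., w:] - cs[..., :-w]


def _panel_array(history, symptoms):
    """(P, S, T) array restricted to ``symptoms``, from panel or 2-D history."""
    if isinstance(history, SymptomPanel):
        idx = {s: i for i, s in enumerate(history.symptoms)}
        missing = [s for s in symptoms if s not in idx]
        if missing:
            raise KeyError(f"symptoms missing from panel: {missing}")
        return history.data[:, [idx[s] for s in symptoms], :]
    if isinstance(history, pd.DataFrame):
        missing = [s for s in symptoms if s not in history.index]
        if missing:
            raise KeyError(f"symptoms missing from history: {missing}")
        return history.loc[list(symptoms)].to_numpy()[None, :, :]
    raise TypeError("history must be a SymptomPanel or a symptom × day DataFrame")


def diagnose(history, rule: DiagnosisRule) -> np.ndarray:
    """Apply a diagnosis rule; returns a boolean per person.

    ``history`` is a :class:`SymptomPanel` (vectorized over persons) or a
    single-person symptom × day DataFrame (returns a length-1 array).
    """
    arr = _panel_array(history, rule.symptoms)
    P, S, T = arr.shape
    w = rule.window
    if T < w:
        logger.warning(
            "history of %d days cannot satisfy a %d-day window for %s",
            T, w, rule.disorder,
        )
        return np.zeros(P, dtype=bool)
    core_pos = [rule.symptoms.index(s) for s in rule.cores]
    if rule.criterion == "every-day":
        if rule.fixed_set:
            # same identity every day: >= min_count symptoms each active on
            # all w days of some run
            sym_runs = _window_sums(arr, w) == w  # (P, S, T-w+1)
            enough = sym_runs.sum(axis=1) >= rule.min_count  # (P, T-w+1)
        else:
            counts = arr.sum(axis=1)  # (P, T)
            daily = counts >= rule.min_count
            if core_pos and not rule.core_whole_window:
                daily &= arr[:, core_pos, :].any(axis=1)
            enough = _window_sums(daily.astype(float), w) == w
        if core_pos and (rule.core_whole_window or rule.fixed_set):
            core_any = arr[:, core_pos, :].any(axis=1).astype(float)
            enough &= _window_sums(core_any, w) >= 1
        return enough.any(axis=1)
    # most-days criterion
    day_thresh = rule.day_majority * w
    counts = arr.sum(axis=1)
    day_ok = counts > rule.symptom_majority * S
    ok_ws = _window_sums(day_ok.astype(float), w) > day_thresh  # (P, T-w+1)
    for cp in core_pos:
        ok_ws &= _window_sums(arr[:, cp, :].astype(float), w) > day_thresh
    return ok_ws.any(axis=1)


def diagnose_mde(history, rule: DiagnosisRule) -> np.ndarray:
    """MDE-style diagnosis: consecutive-day episode criterion."""
    if rule.criterion != "every-day":
        raise ValueError("MDE-style diagnosis requires the every-day criterion")
    return diagnose(history, rule)


def diagnose_gad(history, rule: DiagnosisRule) -> np.ndarray:
    """GAD-style diagnosis: most-symptoms-most-days chronicity criterion."""
    if rule.criterion != "most-days":
        raise ValueError("GAD-style diagnosis requires the most-days criterion")
    return diagnose(history, rule)


def odds_ratio(d1: np.ndarray, d2: np.ndarray):
    """Odds ratio of two binary diagnosis vectors.

    Haldane 0.5 continuity correction is applied to all cells iff any
    cell is zero (logged).  Returns (or, unstable_flag).
    """
    d1 = np.asarray(d1, dtype=bool)
    d2 = np.asarray(d2, dtype=bool)
    n11 = float(np.sum(d1 & d2))
    n10 = float(np.sum(d1 & ~d2))
    n01 = float(np.sum(~d1 & d2))
    n00 = float(np.sum(~d1 & ~d2))
    unstable = (n11 + n10 == 0) or (n01 + n00 == 0) or (n11 + n01 == 0) or (n10 + n00 == 0)
    if unstable:
        logger.warning("degenerate diagnosis margins: odds ratio flagged unstable")
    if min(n11, n10, n01, n00) == 0:
        logger.info("zero cell in 2×2 table: applying Haldane 0.5 correction")
        n11, n10, n01, n00 = n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5
    return (n11 * n00) / (n10 * n01), unstable


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for a persons × items score table.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total).
    """
    items = np.asarray(items, dtype=float)
    k = items.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least two items")
    item_var = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


def population_statistics(panel: SymptomPanel, rules) -> PopulationStats:
    """Prevalence per rule, odds ratio of the first two rules, final-day alpha."""
    rules = list(rules)
    if len(rules) < 2:
        raise ValueError("need two diagnosis rules for an odds ratio")
    diag = {r.disorder: diagnose(panel, r) for r in rules}
    prevalence = {d: float(v.mean()) for d, v in diag.items()}
    od, unstable = odds_ratio(diag[rules[0].disorder], diag[rules[1].disorder])
    alpha = cronbach_alpha(panel.data[:, :, -1])
    return PopulationStats(
        prevalence=prevalence, odds_ratio=od, alpha=alpha, or_unstable=unstable
    )


def plausibility_check(stats: PopulationStats, ranges: PlausibleRanges):
    """Per-statistic closed-interval checks plus their conjunction.

    Returns a dict with one boolean per statistic and key ``overall``.
    """
    out = {}
    for d, (lo, hi) in ranges.prevalence.items():
        out[f"prevalence_{d}"] = bool(lo <= stats.prevalence.get(d, math.nan) <= hi)
    out["odds_ratio"] = bool(ranges.odds_ratio[0] <= stats.odds_ratio <= ranges.odds_ratio[1])
    out["alpha"] = bool(ranges.alpha[0] <= stats.alpha <= ranges.alpha[1])
    out["overall"] = all(v for k, v in out.items())
    return out


def replication_study(
    spec: DynamicsSpec,
    rules,
    n_reps: int,
    n_persons: int,
    T: int,
    seed,
    parameter_mode: str = "original",
    ranges: PlausibleRanges | None = None,
):
    """Replicate the population simulation and collect Table-2-style output.

    ``parameter_mode="shuffled"`` permutes the intact (b_i, c_i) pairs
    across symptoms anew in every replicate — the specificity control
    asking whether plausible statistics require the right parameters on
    the right symptoms, not just the network architecture.

    Returns
    -------
    (DataFrame, dict)
        Per-replicate statistics and a summary with means, SDs, the
        percentage of replicates inside each plausible range, and the
        percentage jointly plausible on all statistics.
    """
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    if parameter_mode not in ("original", "shuffled"):
        raise ValueError("parameter_mode must be 'original' or 'shuffled'")
    from symptomnet.synthetic_data import shuffle_params  # local: avoid cycle

    ranges = ranges or PlausibleRanges()
    rules = list(rules)
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_reps):
        sim_seed = int(rng.integers(2**31))
        shuf_seed = int(rng.integers(2**31))
        rep_spec = spec
        if parameter_mode == "shuffled":
            params = pd.DataFrame(
                {"b": [spec.b[s] for s in spec.symptoms],
                 "c": [spec.c[s] for s in spec.symptoms]},
                index=list(spec.symptoms),
            )
            shuffled = shuffle_params(params, shuf_seed)
            rep_spec = replace(
                spec, b=shuffled["b"].to_dict(), c=shuffled["c"].to_dict()
            )
        panel = simulate_population(rep_spec, n_persons, T, sim_seed)
        stats = population_statistics(panel, rules)
        checks = plausibility_check(stats, ranges)
        rec = {"replicate": rep, "odds_ratio": stats.odds_ratio, "alpha": stats.alpha}
        for d, v in stats.prevalence.items():
            rec[f"prevalence_{d}"] = v
        for k, v in checks.items():
            rec[f"in_range_{k}" if k != "overall" else "plausible_overall"] = v
        records.append(rec)
    df = pd.DataFrame(records)
    stat_cols = [c for c in df.columns if c.startswith(("prevalence_", "odds_ratio", "alpha"))]
    summary = {"mode": parameter_mode, "n_reps": n_reps}
    for c in stat_cols:
        summary[f"{c}_mean"] = float(df[c].mean())
        summary[f"{c}_sd"] = float(df[c].std(ddof=1)) if n_reps > 1 else 0.0
    for c in df.columns:
        if c.startswith("in_range_"):
            summary[f"pct_{c}"] = float(100 * df[c].mean())
    summary["pct_plausible_overall"] = float(100 * df["plausible_overall"].mean())
    return df, summary
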