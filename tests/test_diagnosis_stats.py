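"""Diagnosis rules, population statistics, plausibility and replication."""

import numpy as np
import pandas as pd
import pytest

from symptomnet.diagnosis_stats import (
    DiagnosisRule,
    PlausibleRanges,
    PopulationStats,
    cronbach_alpha,
    diagnose_gad,
    diagnose_mde,
    odds_ratio,
    plausibility_check,
    population_statistics,
    replication_study,
)
from symptomnet.dynamics import DynamicsSpec, SymptomPanel, simulate_population
from symptomnet.synthetic_data import mde_gad_fixture


MDE_SYMPTOMS = ("mDep", "mInt", "mWei", "mRep", "mSui", "bSle", "bFat", "bCon", "bMot")
GAD_SYMPTOMS = ("gAnx", "gEve", "gCtr", "gMus", "gIrr", "bSle", "bFat", "bCon", "bMot")


def history(symptoms, T, active: dict):
    """symptom × day DataFrame with given {symptom: day-range} activations."""
    df = pd.DataFrame(0, index=list(symptoms), columns=range(T))
    for s, (lo, hi) in active.items():
        df.loc[s, lo:hi - 1] = 1
    return df


@pytest.fixture(scope="module")
def mde_rule(fixture_rules):
    return fixture_rules[0]


@pytest.fixture(scope="module")
def gad_rule(fixture_rules):
    return fixture_rules[1]


class TestDiagnoseMDE:
    def test_five_symptoms_with_core_fourteen_days(self, mde_rule):
        h = history(
            MDE_SYMPTOMS, 40,
            {s: (10, 24) for s in ("mDep", "mWei", "mRep", "bSle", "bFat")},
        )
        assert diagnose_mde(h, mde_rule)[0]

    def test_thirteen_days_insufficient(self, mde_rule):
        h = history(
            MDE_SYMPTOMS, 40,
            {s: (10, 23) for s in ("mDep", "mWei", "mRep", "bSle", "bFat")},
        )
        assert not diagnose_mde(h, mde_rule)[0]

    def test_no_core_symptom_never_diagnosed(self, mde_rule):
        h = history(
            MDE_SYMPTOMS, 40,
            {s: (5, 25) for s in ("mWei", "mRep", "mSui", "bSle", "bFat")},
        )
        assert not diagnose_mde(h, mde_rule)[0]

    def test_symptom_identity_may_vary_across_days(self, mde_rule):
        # 5-of-9 holds daily but the fifth symptom changes halfway
        act = {s: (0, 14) for s in ("mDep", "mWei", "mRep", "bSle")}
        act["bFat"] = (0, 7)
        act["bCon"] = (7, 14)
        assert diagnose_mde(history(MDE_SYMPTOMS, 20, act), mde_rule)[0]
        strict = DiagnosisRule(
            **{**mde_rule.__dict__, "fixed_set": True}
        )
        assert not diagnose_mde(history(MDE_SYMPTOMS, 20, act), strict)[0]

    def test_missing_symptom_column_rejected(self, mde_rule):
        h = history(MDE_SYMPTOMS[:-1], 20, {})
        with pytest.raises(KeyError):
            diagnose_mde(h, mde_rule)

    def test_monotone_in_symptom_days(self, mde_rule):
        base = {s: (10, 24) for s in ("mDep", "mWei", "mRep", "bSle", "bFat")}
        h0 = history(MDE_SYMPTOMS, 40, base)
        h1 = history(MDE_SYMPTOMS, 40, {**base, "mSui": (0, 40)})
        assert diagnose_mde(h0, mde_rule)[0] <= diagnose_mde(h1, mde_rule)[0]


class TestDiagnoseGAD:
    def test_all_symptoms_182_days(self, gad_rule):
        h = history(GAD_SYMPTOMS, 200, {s: (1, 183) for s in GAD_SYMPTOMS})
        assert diagnose_gad(h, gad_rule)[0]

    def test_181_day_history_too_short_for_window(self, gad_rule):
        h = history(GAD_SYMPTOMS, 181, {s: (0, 181) for s in GAD_SYMPTOMS})
        assert not diagnose_gad(h, gad_rule)[0]

    def test_cores_alone_fail_symptom_majority(self, gad_rule):
        # cores near-always active, but only 2 further symptoms ever on:
        # the >50%-of-symptoms-on->50%-of-days condition cannot hold
        act = {s: (0, 182) for s in ("gAnx", "gEve", "gCtr")}
        act.update({"gMus": (0, 30), "gIrr": (0, 30)})
        assert not diagnose_gad(history(GAD_SYMPTOMS, 200, act), gad_rule)[0]

    def test_most_days_tolerates_gaps(self, gad_rule):
        # on 100 of 182 days everything is active: strict majority of days
        df = pd.DataFrame(0, index=list(GAD_SYMPTOMS), columns=range(190))
        on_days = list(range(0, 182, 2)) + list(range(1, 20, 2))
        for s in GAD_SYMPTOMS:
            df.loc[s, on_days] = 1
        assert diagnose_gad(df, gad_rule)[0]

    def test_short_history_cannot_qualify(self, gad_rule):
        h = history(GAD_SYMPTOMS, 100, {s: (0, 100) for s in GAD_SYMPTOMS})
        assert not diagnose_gad(h, gad_rule)[0]


class TestPopulationStatistics:
    def test_odds_ratio_arithmetic(self):
        d1 = np.repeat([1, 1, 0, 0], [30, 10, 10, 50]).astype(bool)
        d2 = np.repeat([1, 0, 1, 0], [30, 10, 10, 50]).astype(bool)
        odr, unstable = odds_ratio(d1, d2)
        assert odr == pytest.approx(15.0)
        assert not unstable

    def test_independent_diagnoses_or_one(self):
        d1 = np.repeat([1, 1, 0, 0], [25, 25, 25, 25]).astype(bool)
        d2 = np.repeat([1, 0, 1, 0], [25, 25, 25, 25]).astype(bool)
        assert odds_ratio(d1, d2)[0] == pytest.approx(1.0)

    def test_or_symmetric_in_disorders(self):
        rng = np.random.default_rng(0)
        d1, d2 = rng.random(500) < 0.2, rng.random(500) < 0.1
        assert odds_ratio(d1, d2)[0] == pytest.approx(odds_ratio(d2, d1)[0])

    def test_haldane_correction_on_zero_cell(self):
        d1 = np.array([1, 1, 0, 0], dtype=bool)
        d2 = np.array([1, 1, 0, 0], dtype=bool)
        odr, _ = odds_ratio(d1, d2)  # two zero cells -> all cells + 0.5
        assert odr == pytest.approx((2.5 * 2.5) / (0.5 * 0.5))

    def test_alpha_of_perfectly_correlated_items(self):
        x = np.random.default_rng(1).integers(0, 2, 200)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_population_statistics_bundle(self, fixture_graph, fixture_rules):
        spec = DynamicsSpec(
            graph=fixture_graph,
            a=0.22,
            b={v: 1.0 for v in fixture_graph.nodes},
            c={v: 4.5 for v in fixture_graph.nodes},
        )
        panel = simulate_population(spec, 300, 200, seed=11)
        stats = population_statistics(panel, fixture_rules)
        assert 0 <= stats.prevalence["MDE"] <= 1
        assert 0 <= stats.prevalence["GAD"] <= 1
        assert stats.odds_ratio > 0
        assert stats.alpha <= 1


class TestPlausibility:
    def test_paper_style_means_all_in_range(self):
        stats = PopulationStats(
            prevalence={"MDE": 0.119, "GAD": 0.024}, odds_ratio=10.081, alpha=0.777
        )
        checks = plausibility_check(stats, PlausibleRanges())
        assert checks["overall"]
        assert all(checks.values())

    def test_out_of_range_prevalence_fails_overall(self):
        stats = PopulationStats(
            prevalence={"MDE": 0.199, "GAD": 0.024}, odds_ratio=10.0, alpha=0.777
        )
        checks = plausibility_check(stats, PlausibleRanges())
        assert not checks["prevalence_MDE"]
        assert not checks["overall"]

    def test_boundary_value_inside_closed_interval(self):
        stats = PopulationStats(
            prevalence={"MDE": 0.15, "GAD": 0.05}, odds_ratio=15.0, alpha=0.6
        )
        assert plausibility_check(stats, PlausibleRanges())["overall"]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            PlausibleRanges(odds_ratio=(10.0, 5.0))


@pytest.fixture(scope="module")
def small_spec(fixture_graph):
    return DynamicsSpec(
        graph=fixture_graph,
        a=0.22,
        b={v: 1.0 for v in fixture_graph.nodes},
        c={v: 4.5 for v in fixture_graph.nodes},
    )


class TestReplicationStudy:
    def test_fixed_seed_reproducible(self, small_spec, fixture_rules):
        df1, s1 = replication_study(small_spec, fixture_rules, 2, 100, 200, 5)
        df2, s2 = replication_study(small_spec, fixture_rules, 2, 100, 200, 5)
        pd.testing.assert_frame_equal(df1, df2)
        assert s1 == s2

    def test_shuffling_identical_params_is_noop(self, small_spec, fixture_rules):
        # all (b,c) pairs equal: permutation invariance of the spec
        df_o, _ = replication_study(
            small_spec, fixture_rules, 2, 100, 200, 5, "original"
        )
        df_s, _ = replication_study(
            small_spec, fixture_rules, 2, 100, 200, 5, "shuffled"
        )
        pd.testing.assert_frame_equal(df_o, df_s)

    def test_invalid_mode_rejected(self, small_spec, fixture_rules):
        with pytest.raises(ValueError):
            replication_study(small_spec, fixture_rules, 1, 50, 50, 0, "scrambled")


class TestDurationAsymmetry:
    def test_gad_prevalence_lower_despite_commoner_symptoms(self, fixture_rules):
        """The six-month most-days criterion suppresses GAD diagnoses even
        when GAD symptoms are more active than MDE symptoms."""
        table, rules, _ = mde_gad_fixture()
        from symptomnet.incidence_model import project_to_symptom_graph

        g = project_to_symptom_graph(table)
        mde_set = set(rules[0].symptoms) - set(rules[1].symptoms)
        b = {v: 1.05 for v in g.nodes}
        c = {v: (4.6 if v in mde_set else 4.4) for v in g.nodes}
        spec = DynamicsSpec(graph=g, a=0.22, b=b, c=c)
        panel = simulate_population(spec, 1500, 365, seed=21)
        gad_idx = [list(spec.symptoms).index(s) for s in rules[1].symptoms]
        mde_idx = [list(spec.symptoms).index(s) for s in rules[0].symptoms]
        gad_rate = panel.data[:, gad_idx, :].mean()
        mde_rate = panel.data[:, mde_idx, :].mean()
        assert gad_rate >= mde_rate  # symptom level: GAD at least as common
        stats = population_statistics(panel, rules)
        assert stats.prevalence["GAD"] < stats.prevalence["MDE"]
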