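import numpy as np
import pandas as pd
import pytest

from obmatch import (SimulationConfig, apply_min_survival_filter,
                     build_risk_sets, derive_outcome_records,
                     fit_treatment_hazard, match_risk_set, run_obm,
                     simulate_cohort)
from obmatch.cohort import observed_followup
from obmatch.matching import (UNMATCHED_CALIPER, UNMATCHED_NO_CONTROLS,
                              UNMATCHED_PRIOR_CONTROL, MatchedCohort,
                              MatchedPair, RiskSet, RiskSetMatcher)

from conftest import FixedScores, make_cohort
from oracles import assignment_bruteforce, sequential_obm_bruteforce


class TestBuildRiskSets:
    def test_later_treated_serves_as_earlier_control(self, three_subject_cohort):
        """A patient transplanted at day 200 is a valid control in the
        day-100 risk set."""
        rs = build_risk_sets(three_subject_cohort)
        assert [r.time for r in rs] == [100, 200]
        assert rs[0].treated_ids == [1]
        assert rs[0].control_ids == [2, 3]
        assert rs[1].treated_ids == [2]
        assert rs[1].control_ids == [3]

    def test_dead_subjects_leave_risk_sets(self):
        cohort = make_cohort([
            {"id": 1, "tx_time": 100, "censor_time": 400},
            {"id": 2, "death_time": 50, "censor_time": 400},
            {"id": 3, "censor_time": 400},
        ])
        rs = build_risk_sets(cohort)
        assert rs[0].control_ids == [3]

    def test_exact_boundary_excluded(self):
        """Half-open convention: follow-up exactly equal to the risk-set
        day does not qualify as a control."""
        cohort = make_cohort([
            {"id": 1, "tx_time": 100, "censor_time": 400},
            {"id": 2, "censor_time": 100},
            {"id": 3, "censor_time": 101},
        ])
        rs = build_risk_sets(cohort)
        assert rs[0].control_ids == [3]

    def test_no_transplants_warns_empty(self):
        cohort = make_cohort([{"id": 1}, {"id": 2}])
        with pytest.warns(UserWarning, match="no transplants"):
            assert build_risk_sets(cohort) == []

    def test_membership_matches_bruteforce(self):
        cohort = apply_min_survival_filter(
            simulate_cohort(SimulationConfig(n=200, seed=21)))
        df = cohort.df
        fup = observed_followup(df)
        for rs in build_risk_sets(cohort):
            expected_treated = sorted(df.loc[df["tx_time"] == rs.time, "id"])
            expected_controls = sorted(
                r.id for r, f in zip(df.itertuples(), fup)
                if (pd.isna(r.tx_time) or r.tx_time > rs.time) and f > rs.time)
            assert rs.treated_ids == expected_treated
            assert rs.control_ids == expected_controls


class TestMatchRiskSet:
    def test_nearest_single_match(self):
        rs = RiskSet(time=10, treated_ids=[1], control_ids=[2, 3])
        scores = {1: 0.5, 2: 0.4, 3: 0.9}
        pairs, unmatched = match_risk_set(rs, scores)
        assert len(pairs) == 1 and not unmatched
        assert pairs[0].control_id == 2
        assert pairs[0].distance == pytest.approx(0.1)

    def test_optimal_beats_greedy(self):
        """Optimal assignment takes total cost 0.55 (t2-c1, t1-c2), not
        the greedy 0.65 (t1-c1, t2-c2)."""
        rs = RiskSet(time=5, treated_ids=[1, 2], control_ids=[11, 12])
        scores = {1: 0.5, 2: 0.6, 11: 0.55, 12: 0.0}
        pairs, _ = match_risk_set(rs, scores)
        got = {(p.treated_id, p.control_id) for p in pairs}
        assert got == {(2, 11), (1, 12)}
        assert sum(p.distance for p in pairs) == pytest.approx(0.55)
        greedy, _ = match_risk_set(rs, scores, method="greedy")
        assert sum(p.distance for p in greedy) == pytest.approx(0.65)

    def test_distance_tie_prefers_smaller_control_id(self):
        rs = RiskSet(time=1, treated_ids=[1], control_ids=[7, 2])
        scores = {1: 0.5, 2: 0.5, 7: 0.5}
        pairs, _ = match_risk_set(rs, scores)
        assert pairs[0].control_id == 2

    def test_no_controls_returns_all_unmatched(self):
        rs = RiskSet(time=1, treated_ids=[1, 2], control_ids=[])
        pairs, unmatched = match_risk_set(rs, {1: 0.0, 2: 0.1})
        assert pairs == []
        assert unmatched == {1: UNMATCHED_NO_CONTROLS, 2: UNMATCHED_NO_CONTROLS}

    def test_caliper_voids_distant_pairs(self):
        rs = RiskSet(time=1, treated_ids=[1, 2], control_ids=[11, 12])
        scores = {1: 0.0, 2: 5.0, 11: 0.05, 12: 0.06}
        pairs, unmatched = match_risk_set(rs, scores, caliper=0.5)
        assert [p.treated_id for p in pairs] == [1]
        assert unmatched == {2: UNMATCHED_CALIPER}

    @pytest.mark.parametrize("seed", range(20))
    def test_assignment_cost_matches_factorial_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 7))
        m = int(rng.integers(1, 7))
        treated = list(range(1, k + 1))
        controls = list(range(101, 101 + m))
        scores = {i: float(rng.normal()) for i in treated + controls}
        rs = RiskSet(time=1, treated_ids=treated, control_ids=controls)
        pairs, _ = match_risk_set(rs, scores)
        cost_oracle, _ = assignment_bruteforce(
            [scores[t] for t in treated], [scores[c] for c in controls])
        assert sum(p.distance for p in pairs) == pytest.approx(cost_oracle, abs=1e-9)


class TestRunObm:
    def test_hand_trace_consumed_control_cannot_anchor(self, three_subject_cohort):
        """Identical scores: the day-100 treated takes the smaller-id
        control (subject 2); when subject 2's own transplant day arrives
        it is already matched and anchors no pair."""
        scores = FixedScores({1: 0.0, 2: 0.0, 3: 0.0})
        matcher = RiskSetMatcher().fit(three_subject_cohort, propensity_model=scores)
        assert [(p.treated_id, p.control_id, p.match_time)
                for p in matcher.pairs_] == [(1, 2, 100.0)]
        assert matcher.unmatched_treated_ == {2: UNMATCHED_PRIOR_CONTROL}

    def test_hand_trace_alternative_branch(self):
        """If the day-100 treated takes the never-treated control, the
        day-200 treated still matches the remaining subject."""
        cohort = make_cohort([
            {"id": 1, "tx_time": 100, "censor_time": 400},
            {"id": 2, "tx_time": 200, "censor_time": 400},
            {"id": 3, "censor_time": 400},
        ])
        scores = FixedScores({1: 0.0, 2: 1.0, 3: 0.1})
        matcher = RiskSetMatcher().fit(cohort, propensity_model=scores)
        assert [(p.treated_id, p.control_id) for p in matcher.pairs_] == [(1, 3), (2, None)] or \
               [(p.treated_id, p.control_id) for p in matcher.pairs_] == [(1, 3)]
        assert matcher.pairs_[0].control_id == 3

    def test_saturation(self):
        """Distinct scores and ample controls: pair count equals the
        number of treated not previously consumed as controls."""
        cohort = apply_min_survival_filter(
            simulate_cohort(SimulationConfig(n=400, seed=23)))
        matcher = RiskSetMatcher().fit(cohort)
        n_prior = sum(1 for v in matcher.unmatched_treated_.values()
                      if v == UNMATCHED_PRIOR_CONTROL)
        n_other = sum(1 for v in matcher.unmatched_treated_.values()
                      if v != UNMATCHED_PRIOR_CONTROL)
        n_treated = cohort.df["tx_time"].notna().sum()
        assert len(matcher.pairs_) + n_prior + n_other == n_treated

    def test_no_anachronism_and_conservation(self):
        cohort = apply_min_survival_filter(
            simulate_cohort(SimulationConfig(n=1000, seed=24)))
        matcher = RiskSetMatcher().fit(cohort)
        df = cohort.df.set_index("id")
        seen = []
        for p in matcher.pairs_:
            seen += [p.treated_id, p.control_id]
            ctrl = df.loc[p.control_id]
            if pd.notna(ctrl["tx_time"]):
                assert ctrl["tx_time"] > p.match_time
            for sid in (p.treated_id, p.control_id):
                s = df.loc[sid]
                fup = min(s["death_time"] if pd.notna(s["death_time"]) else np.inf,
                          s["censor_time"])
                assert fup > p.match_time
        assert len(seen) == len(set(seen)), "a subject appears in two pairs"
        n_unmatched = sum(1 for v in matcher.unmatched_treated_.values()
                          if v != UNMATCHED_PRIOR_CONTROL)
        n_never_used = len(cohort) - len(seen) - n_unmatched
        assert 2 * len(matcher.pairs_) + n_unmatched + n_never_used == len(cohort)

    @pytest.mark.parametrize("seed", range(10))
    def test_sequential_pass_matches_bruteforce(self, seed):
        """Production sequential matching reproduces a naive factorial
        reference on random 12-subject cohorts."""
        df, scores = _random_tiny_cohort(seed)
        cohort = make_cohort(df)
        matcher = RiskSetMatcher().fit(cohort, propensity_model=FixedScores(scores))
        oracle_total, oracle_pairs = sequential_obm_bruteforce(cohort.df, scores)
        assert matcher.total_distance_ == pytest.approx(oracle_total, abs=1e-9)
        assert {(p.treated_id, p.control_id) for p in matcher.pairs_} == \
               {(t, c) for t, c, _ in oracle_pairs}

    def test_greedy_total_distance_not_below_optimal(self):
        cohort = apply_min_survival_filter(
            simulate_cohort(SimulationConfig(n=600, seed=26)))
        model = fit_treatment_hazard(cohort)
        opt = RiskSetMatcher(method="optimal").fit(cohort, propensity_model=model)
        greedy = RiskSetMatcher(method="greedy").fit(cohort, propensity_model=model)
        if len(opt.pairs_) == len(greedy.pairs_):
            assert greedy.total_distance_ >= opt.total_distance_ - 1e-9


class TestOutcomeRecords:
    def test_control_censored_without_event(self):
        cohort = make_cohort([
            {"id": 1, "tx_time": 100, "censor_time": 600},
            {"id": 2, "censor_time": 500},
        ])
        matched = MatchedCohort(pairs=[MatchedPair(1, 2, 100, 0.0)])
        rec = derive_outcome_records(matched, cohort, "death")
        ctrl = rec[rec["id"] == 2].iloc[0]
        assert ctrl["time_from_match"] == 400
        assert ctrl["event"] == 0

    def test_crossover_policies(self):
        """Control matched at 100, transplanted itself at 300, dies at
        600: censor-at-crossover gives (200, 0); intention-to-treat
        gives (500, 1)."""
        cohort = make_cohort([
            {"id": 1, "tx_time": 100, "censor_time": 800},
            {"id": 2, "tx_time": 300, "death_time": 600, "censor_time": 800},
        ])
        matched = MatchedCohort(pairs=[MatchedPair(1, 2, 100, 0.0)])
        cens = derive_outcome_records(matched, cohort, "death", "censor_at_crossover")
        itt = derive_outcome_records(matched, cohort, "death", "itt")
        c = cens[cens["id"] == 2].iloc[0]
        i = itt[itt["id"] == 2].iloc[0]
        assert (c["time_from_match"], c["event"]) == (200, 0)
        assert (i["time_from_match"], i["event"]) == (500, 1)

    def test_death_censors_mace(self):
        cohort = make_cohort([
            {"id": 1, "tx_time": 50, "censor_time": 900},
            {"id": 2, "death_time": 400, "censor_time": 900},
        ])
        matched = MatchedCohort(pairs=[MatchedPair(1, 2, 50, 0.0)])
        rec = derive_outcome_records(matched, cohort, "mace")
        ctrl = rec[rec["id"] == 2].iloc[0]
        assert (ctrl["time_from_match"], ctrl["event"]) == (350, 0)

    def test_times_match_bruteforce_recount(self):
        cohort = apply_min_survival_filter(
            simulate_cohort(SimulationConfig(n=500, seed=27)))
        matcher = RiskSetMatcher().fit(cohort)
        rec = derive_outcome_records(matcher.matched_, cohort, "death")
        df = cohort.df.set_index("id")
        mtimes = {}
        for p in matcher.pairs_:
            mtimes[p.treated_id] = (p.match_time, "transplant")
            mtimes[p.control_id] = (p.match_time, "control")
        for r in rec.itertuples():
            s = df.loc[r.id]
            m, role = mtimes[r.id]
            cens = s["censor_time"]
            if role == "control" and pd.notna(s["tx_time"]):
                cens = min(cens, s["tx_time"])
            death = s["death_time"] if pd.notna(s["death_time"]) else np.inf
            end = min(death, cens)
            assert r.time_from_match == pytest.approx(end - m)
            assert r.event == int(death <= cens)
        assert (rec["time_from_match"] >= 0).all()

    def test_negative_derived_time_rejected(self):
        cohort = make_cohort([{"id": 1, "tx_time": 100, "censor_time": 400},
                              {"id": 2, "censor_time": 50}])
        bogus = MatchedCohort(pairs=[MatchedPair(1, 2, 100, 0.0)])
        with pytest.raises(ValueError, match="negative"):
            derive_outcome_records(bogus, cohort, "death")

    def test_run_obm_wrapper_returns_matched_cohort(self, three_subject_cohort):
        cohort = apply_min_survival_filter(
            simulate_cohort(SimulationConfig(n=300, seed=28)))
        matched = run_obm(cohort)
        assert isinstance(matched, MatchedCohort)
        assert len(matched.pairs) > 0


def _random_tiny_cohort(seed):
    """Random <=12-subject cohort rows (respecting the time invariants)
    plus preset scores."""
    rng = np.random.default_rng(1000 + seed)
    n = int(rng.integers(6, 13))
    rows, scores = [], {}
    for i in range(1, n + 1):
        censor = int(rng.integers(100, 500))
        row = {"id": i, "censor_time": censor}
        if rng.random() < 0.25:
            row["death_time"] = int(rng.integers(20, censor + 1))
        fup = min(row.get("death_time", np.inf), censor)
        if rng.random() < 0.5 and fup > 15:
            row["tx_time"] = int(rng.integers(10, min(fup, 400)))
        rows.append(row)
        scores[i] = float(np.round(rng.normal(), 2))  # rounding creates ties
    if not any("tx_time" in r for r in rows):
        rows[0]["tx_time"] = 10
    return rows, scores
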