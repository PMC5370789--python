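"""Sequential optimal balanced risk-set matching.

At each distinct transplant day, every newly treated patient is paired
with the alive, uncensored, not-yet-transplanted, not-yet-matched
control whose propensity score is closest, solving the within-risk-set
1:1 assignment problem exactly (minimum total absolute score
difference).  Matched subjects — both roles — are removed from all
later risk sets, so a patient transplanted later may first serve as a
control; if so, their own transplant anchors no new pair.  The matched
cohort resets each subject's outcome clock to the pair's match time,
which is what removes immortal time from the treated/control contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from .cohort import CohortTable, observed_followup
from .propensity import TreatmentHazardModel, fit_treatment_hazard

#: reasons recorded for transplant recipients who end up without a pair
UNMATCHED_NO_CONTROLS = "no_eligible_controls"
UNMATCHED_INSUFFICIENT = "insufficient_controls"
UNMATCHED_CALIPER = "caliper"
UNMATCHED_PRIOR_CONTROL = "previously_matched_as_control"

_TIE_EPS = 1e-12  # deterministic tie-break: prefer the smaller control id


@dataclass
class RiskSet:
    """Treated and eligible-control ids at one transplant day."""

    time: float
    treated_ids: list
    control_ids: list


@dataclass
class MatchedPair:
    treated_id: object
    control_id: object
    match_time: float
    distance: float


@dataclass
class MatchedCohort:
    """1:1 pairs plus the per-subject outcome clock reset to match time."""

    pairs: list = field(default_factory=list)
    unmatched_treated: dict = field(default_factory=dict)  # id -> reason

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, p.treated_id, p.control_id, p.match_time, p.distance)
             for k, p in enumerate(self.pairs)],
            columns=["pair_id", "treated_id", "control_id", "match_time", "distance"],
        )

    @property
    def matched_ids(self) -> set:
        out = set()
        for p in self.pairs:
            out.add(p.treated_id)
            out.add(p.control_id)
        return out


def build_risk_sets(cohort) -> list[RiskSet]:
    """Static risk sets, one per distinct transplant day, ascending.

    Control eligibility at day ``t``: not yet transplanted at ``t``
    (transplant absent or strictly later) and event-free strictly
    beyond ``t`` (half-open convention).  Matching-status bookkeeping
    is sequential and therefore lives in :func:`run_obm`, which
    re-evaluates eligibility as pairs are consumed.
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    tx = df["tx_time"].to_numpy(float)
    fup = observed_followup(df).to_numpy(float)
    ids = df["id"].to_numpy()
    days = np.unique(tx[~np.isnan(tx)])
    if days.size == 0:
        warnings.warn("cohort contains no transplants; no risk sets", stacklevel=2)
        return []
    out = []
    for t in days:
        treated = ids[tx == t]
        eligible = (np.isnan(tx) | (tx > t)) & (fup > t)
        out.append(RiskSet(time=float(t),
                           treated_ids=sorted(treated.tolist()),
                           control_ids=sorted(ids[eligible].tolist())))
    return out


def match_risk_set(riskset: RiskSet, scores, method="optimal", caliper=None):
    """1:1 assignment within one risk set.

    Minimizes the total absolute score difference over treated x
    controls (rectangular assignment: when controls are scarce the
    cheapest subset of treated is matched).  Distance ties break toward
    the smaller control id.  ``caliper`` (score units) voids pairs
    farther apart than that.

    Returns
    -------
    (pairs, unmatched) : list of MatchedPair, dict id -> reason
    """
    treated = list(riskset.treated_ids)
    controls = list(riskset.control_ids)
    if not treated:
        return [], {}
    if not controls:
        return [], {tid: UNMATCHED_NO_CONTROLS for tid in treated}

    ts = np.array([scores[t] for t in treated], float)
    cs = np.array([scores[c] for c in controls], float)
    dist = np.abs(ts[:, None] - cs[None, :])
    # infinitesimal preference for low-id controls makes ties deterministic
    id_rank = np.argsort(np.argsort(np.asarray(controls)))
    cost = dist + _TIE_EPS * id_rank[None, :]
    if caliper is not None:
        penalty = dist.max() + abs(caliper) + 1.0
        cost = np.where(dist > caliper, cost + penalty * 1e6, cost)

    pairs, unmatched = [], {}
    if method == "optimal":
        rows, cols = linear_sum_assignment(cost)
        assigned = dict(zip(rows.tolist(), cols.tolist()))
    elif method == "greedy":
        assigned = {}
        taken = np.zeros(len(controls), bool)
        for i in range(len(treated)):
            free = np.flatnonzero(~taken)
            if free.size == 0:
                break
            j = free[np.argmin(cost[i, free])]
            assigned[i] = int(j)
            taken[j] = True
    else:
        raise ValueError(f"unknown matching method {method!r}")

    for i, tid in enumerate(treated):
        if i not in assigned:
            unmatched[tid] = UNMATCHED_INSUFFICIENT
            continue
        j = assigned[i]
        if caliper is not None and dist[i, j] > caliper:
            unmatched[tid] = UNMATCHED_CALIPER
            continue
        pairs.append(MatchedPair(treated_id=tid, control_id=controls[j],
                                 match_time=riskset.time, distance=float(dist[i, j])))
    return pairs, unmatched


class RiskSetMatcher(BaseEstimator):
    """Sequential optimal risk-set matcher.

    Parameters
    ----------
    covariates : list of str or None
        Propensity covariates (None -> the default registry set).
    method : {"optimal", "greedy"}
        Within-risk-set assignment: exact minimum-cost, or greedy
        nearest-neighbor in treated order (for comparison).
    caliper : float or None
        Maximum allowed score distance, in standard deviations of the
        score over the cohort; None disables it.
    crossover_policy : {"censor_at_crossover", "itt"}
        Whether a matched control is censored at its own later
        transplant when outcome records are derived.

    Attributes
    ----------
    model_ : TreatmentHazardModel — the fitted propensity model.
    scores_ : dict id -> score.
    matched_ : MatchedCohort.
    pairs_ : list of MatchedPair.
    unmatched_treated_ : dict id -> reason.
    """

    def __init__(self, covariates=None, method="optimal", caliper=None,
                 crossover_policy="censor_at_crossover", ties="breslow"):
        self.covariates = covariates
        self.method = method
        self.caliper = caliper
        self.crossover_policy = crossover_policy
        self.ties = ties

    def fit(self, cohort, y=None, propensity_model: TreatmentHazardModel | None = None):
        df = cohort.df if isinstance(cohort, CohortTable) else cohort
        if len(df) == 0:
            raise ValueError("empty cohort")
        model = propensity_model or fit_treatment_hazard(df, self.covariates, ties=self.ties)
        scores = dict(zip(df["id"], model.score_samples(df)))
        caliper_abs = None
        if self.caliper is not None:
            caliper_abs = float(self.caliper) * float(np.std(list(scores.values())))

        tx = df["tx_time"].to_numpy(float)
        fup = observed_followup(df).to_numpy(float)
        ids = df["id"].to_numpy()
        days = np.unique(tx[~np.isnan(tx)])

        matched: set = set()
        pairs: list[MatchedPair] = []
        unmatched: dict = {}
        for t in days:
            newly = ids[(tx == t)]
            treated_today = sorted(i for i in newly.tolist() if i not in matched)
            for i in newly.tolist():
                if i in matched:
                    unmatched[i] = UNMATCHED_PRIOR_CONTROL
            if not treated_today:
                continue
            elig = (np.isnan(tx) | (tx > t)) & (fup > t)
            control_ids = sorted(i for i in ids[elig].tolist() if i not in matched)
            rs = RiskSet(time=float(t), treated_ids=treated_today, control_ids=control_ids)
            new_pairs, new_unmatched = match_risk_set(
                rs, scores, method=self.method, caliper=caliper_abs)
            pairs.extend(new_pairs)
            unmatched.update(new_unmatched)
            for p in new_pairs:
                matched.add(p.treated_id)
                matched.add(p.control_id)

        self.model_ = model
        self.scores_ = scores
        self.pairs_ = pairs
        self.unmatched_treated_ = unmatched
        self.matched_ = MatchedCohort(pairs=pairs, unmatched_treated=unmatched)
        self._cohort_df = df
        return self

    def outcome_records(self, outcome_type="death", crossover_policy=None) -> pd.DataFrame:
        policy = crossover_policy or self.crossover_policy
        return derive_outcome_records(self.matched_, self._cohort_df, outcome_type, policy)

    @property
    def total_distance_(self) -> float:
        return float(sum(p.distance for p in self.pairs_))


def run_obm(cohort, model: TreatmentHazardModel | None = None, *,
            method="optimal", caliper=None,
            crossover_policy="censor_at_crossover") -> MatchedCohort:
    """Run the full sequential matching pass; see :class:`RiskSetMatcher`."""
    matcher = RiskSetMatcher(method=method, caliper=caliper,
                             crossover_policy=crossover_policy)
    matcher.fit(cohort, propensity_model=model)
    return matcher.matched_


def derive_outcome_records(matched: MatchedCohort, cohort, outcome_type="death",
                           crossover_policy="censor_at_crossover") -> pd.DataFrame:
    """Per-subject outcome records with the clock reset to match time.

    For the death outcome a subject's record ends at
    ``min(death, censor)``; for the cardiac-event (MACE) outcome,
    event-free death additionally censors.  Under
    ``censor_at_crossover`` a matched control is censored at its own
    later transplant; under ``itt`` crossover is ignored.
    """
    if outcome_type not in ("death", "mace"):
        raise ValueError(f"unknown outcome {outcome_type!r}")
    if crossover_policy not in ("censor_at_crossover", "itt"):
        raise ValueError(f"unknown crossover policy {crossover_policy!r}")
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    sub = df.set_index("id")
    rows = []
    for pair_id, p in enumerate(matched.pairs):
        for arm, sid in (("transplant", p.treated_id), ("control", p.control_id)):
            s = sub.loc[sid]
            event_time = s["death_time"] if outcome_type == "death" else s["mace_time"]
            event_time = np.inf if pd.isna(event_time) else float(event_time)
            if outcome_type == "mace" and event_time <= p.match_time:
                # cardiac events are not terminal, so a subject can carry
                # one from before the match date; only incident events
                # after the clock reset count
                event_time = np.inf
            cens = float(s["censor_time"])
            if outcome_type == "mace" and not pd.isna(s["death_time"]):
                cens = min(cens, float(s["death_time"]))
            if (arm == "control" and crossover_policy == "censor_at_crossover"
                    and not pd.isna(s["tx_time"])):
                cens = min(cens, float(s["tx_time"]))
            end = min(event_time, cens)
            event = int(event_time <= cens)
            t = end - p.match_time
            if t < 0:
                raise ValueError(
                    f"negative time from match for subject {sid} (pair {pair_id}); "
                    "risk-set eligibility was violated upstream")
            rows.append((pair_id, sid, arm, t, event, outcome_type))
    return pd.DataFrame(rows, columns=["pair_id", "id", "arm", "time_from_match",
                                       "event", "outcome_type"])


def matched_analysis_frame(matched: MatchedCohort, cohort, outcome_type="death",
                           crossover_policy="censor_at_crossover",
                           covariates=None) -> pd.DataFrame:
    """Outcome records joined with baseline covariates and an ``arm``
    indicator (transplant = 1), ready for a Cox fit."""
    from .cohort import OUTCOME_COVARIATES, design_matrix

    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    rec = derive_outcome_records(matched, df, outcome_type, crossover_policy)
    names = list(covariates) if covariates is not None else list(OUTCOME_COVARIATES)
    X = design_matrix(df, names)
    X = X.set_index(df["id"])
    out = rec.join(X, on="id")
    out["arm"] = (out["arm"] == "transplant").astype(int)
    return out


def matched_to_csv(matched: MatchedCohort, cohort, path,
                   crossover_policy="censor_at_crossover") -> None:
    """Write the matched cohort: one row per matched subject with both
    outcome clocks."""
    death = derive_outcome_records(matched, cohort, "death", crossover_policy)
    mace = derive_outcome_records(matched, cohort, "mace", crossover_policy)
    merged = death.merge(
        mace[["pair_id", "id", "time_from_match", "event"]],
        on=["pair_id", "id"], suffixes=("_death", "_mace"))
    dist = {k: p.distance for k, p in enumerate(matched.pairs)}
    mtime = {k: p.match_time for k, p in enumerate(matched.pairs)}
    merged["match_time"] = merged["pair_id"].map(mtime)
    merged["distance"] = merged["pair_id"].map(dist)
    merged = merged.rename(columns={"arm": "role"})
    cols = ["pair_id", "role", "id", "match_time",
            "time_from_match_death", "event_death",
            "time_from_match_mace", "event_mace", "distance"]
    merged[cols].to_csv(path, index=False)
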