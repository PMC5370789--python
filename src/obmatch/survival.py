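"""Matched outcome analysis: Kaplan–Meier estimation, weighted log-rank
tests, crude rates, Cox hazard models, and subgroup/interaction analyses.

The primary contrast is transplant arm versus matched control arm with
the clock starting at match time.  The Peto–Peto modification of the
Gehan–Wilcoxon test weights each event time by the pooled-sample
modified survival estimate, emphasising early differences — appropriate
when hazards cross or proportionality is doubtful early after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OUTCOME_COVARIATES, CohortTable, design_matrix, observed_followup
from .cox import CoxResult, fit_cox_newton

AGE_SUBGROUP_BINS = ((18, 39), (40, 49), (50, 59), (60, np.inf))


# ---------------------------------------------------------------------------
# Kaplan–Meier

@dataclass
class SurvivalCurve:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): step-function evaluation."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimator: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("no records")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t)
    n_at_risk, n_events, n_censored = [], [], []
    at_risk = len(t)
    for u in uniq:
        mask = t == u
        d = int(e[mask].sum())
        c = int(mask.sum()) - d
        n_at_risk.append(at_risk)
        n_events.append(d)
        n_censored.append(c)
        at_risk -= int(mask.sum())
    n_at_risk = np.array(n_at_risk, float)
    n_events = np.array(n_events, float)
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    return SurvivalCurve(event_times=uniq, n_at_risk=n_at_risk,
                         n_events=n_events,
                         n_censored=np.array(n_censored, float),
                         survival=surv)


# ---------------------------------------------------------------------------
# Weighted log-rank

@dataclass
class WeightedLogRankResult:
    statistic: float
    df: int
    p_value: float
    weight_scheme: str


def peto_peto_test(times, events, groups, weight_scheme="peto") -> WeightedLogRankResult:
    """Two-sample weighted log-rank test.

    With ``weight_scheme="peto"`` the weight at event time t_i is the
    pooled-sample Peto–Peto modified survival estimate
    S~(t_i) = prod_{t_j <= t_i} (1 - d_j / (n_j + 1)); with
    ``"logrank"`` all weights are 1 (the standard log-rank).  The
    statistic is [sum w_i (d_1i - e_1i)]^2 / sum w_i^2 v_i with the
    hypergeometric mean e_1i and variance v_i, referred to chi-square(1).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"exactly two arms required, got {labels.tolist()}")
    if events.sum() == 0:
        raise ValueError("no events in either arm")
    g1 = groups == labels[0]

    # counts at each distinct event time (sorted-array bisection)
    uniq, d_total = np.unique(times[events == 1], return_counts=True)
    d_total = d_total.astype(float)
    et1 = np.sort(times[g1 & (events == 1)])
    d_1 = (np.searchsorted(et1, uniq, "right")
           - np.searchsorted(et1, uniq, "left")).astype(float)
    st = np.sort(times)
    n_total = (len(st) - np.searchsorted(st, uniq, "left")).astype(float)
    st1 = np.sort(times[g1])
    n_1 = (len(st1) - np.searchsorted(st1, uniq, "left")).astype(float)

    if weight_scheme == "peto":
        w = np.cumprod(1.0 - d_total / (n_total + 1.0))
    elif weight_scheme == "logrank":
        w = np.ones_like(d_total)
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")

    e_1 = d_total * n_1 / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(n_total > 1,
                     d_total * (n_1 / n_total) * (1 - n_1 / n_total)
                     * (n_total - d_total) / (n_total - 1),
                     0.0)
    num = float(np.sum(w * (d_1 - e_1))) ** 2
    den = float(np.sum(w ** 2 * v))
    statistic = num / den if den > 0 else 0.0
    p = float(stats.chi2.sf(statistic, 1)) if den > 0 else 1.0
    return WeightedLogRankResult(statistic=float(statistic), df=1,
                                 p_value=p, weight_scheme=weight_scheme)


# ---------------------------------------------------------------------------
# Crude rates

def crude_rate(n_events: int, n_total: int) -> float:
    """Events per group size as a percentage, rounded half-up to one
    decimal (19.25 -> 19.3)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_events <= n_total:
        raise ValueError("n_events must lie in [0, n_total]")
    pct = Decimal(100 * n_events) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Cox fits

@dataclass
class CoxFit:
    """Hazard-model summary: one row per covariate."""

    summary: pd.DataFrame  # name, beta, se, hr, ci95_low, ci95_high, p
    loglik: float
    ties_method: str
    converged: bool
    n: int
    n_events: int
    result: CoxResult

    def coef(self, name: str) -> float:
        return float(self.summary.set_index("name").loc[name, "beta"])

    def hr(self, name: str) -> float:
        return float(self.summary.set_index("name").loc[name, "hr"])

    def ci95(self, name: str) -> tuple[float, float]:
        row = self.summary.set_index("name").loc[name]
        return float(row["ci95_low"]), float(row["ci95_high"])


def _wrap(res: CoxResult) -> CoxFit:
    ci = res.ci95
    summary = pd.DataFrame({
        "name": res.names, "beta": res.beta, "se": res.se, "hr": res.hr,
        "ci95_low": ci[:, 0], "ci95_high": ci[:, 1], "p": res.p_values,
    })
    return CoxFit(summary=summary, loglik=res.loglik, ties_method=res.ties,
                  converged=res.converged, n=res.n, n_events=res.n_events,
                  result=res)


def fit_cox(records: pd.DataFrame, covariates, ties_method="breslow",
            time_col="time_from_match", event_col="event",
            cluster_col=None) -> CoxFit:
    """Cox proportional-hazards fit on an outcome-record frame.

    ``records`` must hold the follow-up time, the binary event flag and
    one numeric column per requested covariate (use
    :func:`obmatch.matching.matched_analysis_frame` to assemble the
    matched analysis with its ``arm`` indicator and adjustment set).
    Plain Wald standard errors by default; ``cluster_col`` (e.g.
    ``"pair_id"``) switches to the clustered sandwich variance.
    """
    missing = [c for c in list(covariates) + [time_col, event_col]
               if c not in records.columns]
    if missing:
        raise KeyError(f"missing column(s) in records: {missing}")
    X = records[list(covariates)].to_numpy(float)
    time = records[time_col].to_numpy(float)
    event = records[event_col].to_numpy()
    res = fit_cox_newton(time, event, X, names=list(covariates), ties=ties_method)
    if cluster_col is not None:
        from .cox import clustered_covariance
        res.cov = clustered_covariance(res, time, event, X,
                                       records[cluster_col].to_numpy())
        res.se = np.sqrt(np.clip(np.diag(res.cov), 0, None))
    return _wrap(res)


def naive_ever_treated_cox(cohort, covariates=None, ties_method="breslow") -> CoxFit:
    """Deliberately biased comparator: ever-transplanted as a time-fixed
    covariate with time measured from dialysis initiation.

    Patients must survive to transplant, so the person-time between
    dialysis start and transplant is misclassified as exposed —
    immortal time — which manufactures a spurious protective effect.
    This fit exists to demonstrate the bias that risk-set matching
    removes.
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    names = list(covariates) if covariates is not None else list(OUTCOME_COVARIATES)
    rec = design_matrix(df, names)
    rec = rec.assign(arm=df["tx_time"].notna().astype(int).to_numpy(),
                     time=observed_followup(df).to_numpy(float),
                     event=df["death_time"].notna().astype(int).to_numpy())
    return fit_cox(rec, ["arm"] + names, ties_method=ties_method,
                   time_col="time", event_col="event")


# ---------------------------------------------------------------------------
# Subgroups

@dataclass
class SubgroupResult:
    subgroup: str
    level: str
    n: int
    n_events: int
    hr: float
    ci95_low: float
    ci95_high: float
    p: float
    p_interaction: float
    flag: str = ""


def default_subgroup_defs(records: pd.DataFrame) -> dict:
    """Default subgroup layout: age bands, sex, insurance, modality and
    the nine comorbidity flags (levels as boolean masks)."""
    defs: dict[str, dict] = {}
    age = records["age"]
    defs["age"] = {
        f"{lo}-{hi}" if np.isfinite(hi) else f">={lo}": (age >= lo) & (age <= hi)
        for lo, hi in AGE_SUBGROUP_BINS
    }
    for var, lab0, lab1 in (("sex", "F", "M"), ("insurance", "NHI", "MedicalAid"),
                            ("modality", "HD", "PD")):
        defs[var] = {lab1: records[var] == 1, lab0: records[var] == 0}
    for flag in ["dm", "mi", "chf", "pvd", "cvd", "copd", "pud", "liver", "cancer"]:
        defs[flag] = {"yes": records[flag] == 1, "no": records[flag] == 0}
    return defs


def _own_columns(subgroup: str) -> list[str]:
    return ["age"] if subgroup == "age" else [subgroup]


def subgroup_analysis(records: pd.DataFrame, subgroup_defs=None,
                      covariates=None, ties_method="breslow") -> pd.DataFrame:
    """Arm hazard ratio per subgroup level plus an interaction test.

    Each level is fit with the multivariate adjustment set minus the
    subgroup's own variable; the interaction p-value is a Wald block
    test of the arm x level product terms in the pooled (adjusted)
    model.  Levels without events are flagged, not dropped.
    """
    adj = list(covariates) if covariates is not None else list(OUTCOME_COVARIATES)
    defs = subgroup_defs if subgroup_defs is not None else default_subgroup_defs(records)
    out = []
    for subgroup, levels in defs.items():
        drop = _own_columns(subgroup)
        adj_sub = [c for c in adj if c not in drop]
        p_int = _interaction_p(records, subgroup, levels, adj_sub, ties_method)
        for level, mask in levels.items():
            sub = records.loc[np.asarray(mask, bool)]
            n, n_ev = len(sub), int(sub["event"].sum())
            if n == 0 or n_ev == 0:
                out.append(SubgroupResult(subgroup, level, n, n_ev,
                                          np.nan, np.nan, np.nan, np.nan,
                                          p_int, flag="no_events"))
                continue
            try:
                keep = [c for c in adj_sub if sub[c].nunique() > 1]
                with warnings.catch_warnings():
                    # sparse levels separate routinely; the flag column
                    # already records non-convergence
                    warnings.simplefilter("ignore", UserWarning)
                    fit = fit_cox(sub, ["arm"] + keep, ties_method=ties_method)
                lo, hi = fit.ci95("arm")
                out.append(SubgroupResult(
                    subgroup, level, n, n_ev, fit.hr("arm"), lo, hi,
                    float(fit.summary.set_index("name").loc["arm", "p"]), p_int,
                    flag="" if fit.converged else "not_converged"))
            except (ValueError, np.linalg.LinAlgError) as exc:
                out.append(SubgroupResult(subgroup, level, n, n_ev,
                                          np.nan, np.nan, np.nan, np.nan,
                                          p_int, flag=f"fit_failed: {exc}"))
    return pd.DataFrame([vars(r) for r in out])


def _interaction_p(records, subgroup, levels, adj, ties_method) -> float:
    """Wald test of arm x subgroup product terms in the pooled model."""
    level_names = list(levels)
    if len(level_names) < 2:
        return np.nan
    rec = records.copy()
    cols = ["arm"] + adj
    # level dummies (reference = first level) and their arm products
    for name in level_names[1:]:
        mask = np.asarray(levels[name], bool).astype(float)
        dummy = f"_sg_{name}"
        prod = f"_armx_{name}"
        rec[dummy] = mask
        rec[prod] = mask * rec["arm"]
        cols += [dummy, prod]
    cols = [c for c in cols if rec[c].nunique() > 1]
    prod_cols = [c for c in cols if c.startswith("_armx_")]
    if not prod_cols:
        return np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fit = fit_cox(rec, cols, ties_method=ties_method)
    except (ValueError, np.linalg.LinAlgError):
        return np.nan
    idx = [fit.result.names.index(c) for c in prod_cols]
    _, _, p = fit.result.wald_block_test(idx)
    return p
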