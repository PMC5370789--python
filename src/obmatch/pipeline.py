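"""End-to-end pipeline: simulate -> filter -> propensity -> match ->
balance -> outcomes, with a reproducible report bundle.

A single global seed drives every stage; per-stage streams are derived
by hashing the stage name so that unrelated stages do not perturb one
another's draws.  The bundle (CSV tables, JSON summaries, figures and a
run manifest) is enough to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import balance_report
from .cohort import (OUTCOME_COVARIATES, PROPENSITY_COVARIATES, CohortTable,
                     apply_min_survival_filter, read_cohort_csv, write_cohort_csv)
from .matching import RiskSetMatcher, matched_analysis_frame, matched_to_csv
from .plots import forest_plot, km_plot, love_plot
from .propensity import fit_treatment_hazard
from .simulate import SimulationConfig, simulate_cohort
from .survival import (CoxFit, crude_rate, fit_cox, kaplan_meier,
                       naive_ever_treated_cox, peto_peto_test, subgroup_analysis)

log = logging.getLogger("obmatch")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage stream below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    seed: int = 0
    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    min_survival_days: int = 90
    propensity_covariates: list = field(default_factory=lambda: list(PROPENSITY_COVARIATES))
    outcome_covariates: list = field(default_factory=lambda: list(OUTCOME_COVARIATES))
    matching_method: str = "optimal"
    caliper: float | None = None
    crossover_policy: str = "censor_at_crossover"
    outcomes: list = field(default_factory=lambda: ["death", "mace"])
    subgroups: bool = False
    figures: bool = True
    output_dir: str = "obm_output"

    def to_dict(self) -> dict:
        d = dict(vars(self))
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "seed" not in data:
            raise ValueError("config must set a seed")
        return cls.from_dict(data)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``output_dir``.

    Returns a dict of in-memory results keyed by stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    try:
        stage = "simulate"
        if config.cohort_path is not None:
            cohort = read_cohort_csv(config.cohort_path)
            log.info("loaded cohort: %d subjects from %s", len(cohort), config.cohort_path)
        else:
            sim = config.simulation or SimulationConfig()
            sim.seed = derive_seed(config.seed, "simulate")
            cohort = simulate_cohort(sim)
            log.info("simulated cohort: %d subjects", len(cohort))

        stage = "filter"
        n0 = len(cohort)
        cohort = apply_min_survival_filter(cohort, config.min_survival_days)
        log.info("minimum-survival filter (%d days): %d -> %d subjects",
                 config.min_survival_days, n0, len(cohort))
        write_cohort_csv(cohort, out / "cohort.csv")
        results["cohort"] = cohort

        stage = "propensity"
        model = fit_treatment_hazard(cohort, config.propensity_covariates)
        model.to_json(out / "propensity.json")
        log.info("treatment-hazard model: %d transplants, converged=%s",
                 model.n_events_, model.converged_)
        results["propensity"] = model

        stage = "match"
        matcher = RiskSetMatcher(covariates=config.propensity_covariates,
                                 method=config.matching_method,
                                 caliper=config.caliper,
                                 crossover_policy=config.crossover_policy)
        matcher.fit(cohort, propensity_model=model)
        matched = matcher.matched_
        matched_to_csv(matched, cohort, out / "matched.csv", config.crossover_policy)
        log.info("matched %d pairs; %d treated unmatched",
                 len(matched.pairs), len(matched.unmatched_treated))
        results["matched"] = matched
        results["matcher"] = matcher

        stage = "balance"
        report = balance_report(cohort, matched, config.outcome_covariates + ["cci"])
        report.to_csv(out / "balance.csv")
        log.info("mean |SMD| before=%.3f after=%.3f",
                 report.mean_abs_before, report.mean_abs_after)
        results["balance"] = report
        if config.figures:
            love_plot(report, out / "love_plot.png")

        for outcome in config.outcomes:
            stage = f"outcomes_{outcome}"
            rec = matched_analysis_frame(matched, cohort, outcome,
                                         config.crossover_policy,
                                         config.outcome_covariates)
            arms = {"transplant": rec[rec["arm"] == 1], "control": rec[rec["arm"] == 0]}
            curves = {k: kaplan_meier(v["time_from_match"], v["event"])
                      for k, v in arms.items()}
            rates = {k: crude_rate(int(v["event"].sum()), len(v)) for k, v in arms.items()}
            if rec["event"].sum() == 0:
                log.warning("%s: no events in matched records; hazard model "
                            "and test skipped", outcome)
                pd.DataFrame().to_csv(out / f"outcomes_{outcome}.csv", index=False)
                results[f"outcomes_{outcome}"] = {
                    "fit": None, "fit_univariate": None, "curves": curves,
                    "test": None, "crude_rates": rates, "records": rec,
                }
                continue
            # covariates can degenerate in the matched subset
            adj = [c for c in config.outcome_covariates if rec[c].nunique() > 1]
            dropped = sorted(set(config.outcome_covariates) - set(adj))
            if dropped:
                log.info("%s: dropped constant covariate(s) %s", outcome, dropped)
            fit = fit_cox(rec, ["arm"] + adj)
            uni = fit_cox(rec, ["arm"])
            test = peto_peto_test(rec["time_from_match"], rec["event"], rec["arm"])
            fit.summary.to_csv(out / f"outcomes_{outcome}.csv", index=False)
            results[f"outcomes_{outcome}"] = {
                "fit": fit, "fit_univariate": uni, "curves": curves,
                "test": test, "crude_rates": rates, "records": rec,
            }
            log.info("%s: HR(arm)=%.3f, Peto-Peto p=%.2g, crude rates %s",
                     outcome, fit.hr("arm"), test.p_value, rates)
            if config.figures:
                km_plot(curves, out / f"km_{outcome}.png", title=outcome)
            if config.subgroups:
                stage = f"subgroups_{outcome}"
                sg = subgroup_analysis(rec, covariates=config.outcome_covariates)
                sg.to_csv(out / f"subgroups_{outcome}.csv", index=False)
                results[f"subgroups_{outcome}"] = sg
                if config.figures:
                    forest_plot(sg, out / f"forest_{outcome}.png", title=outcome)

        stage = "naive"
        if cohort.df["death_time"].notna().any():
            adj = [c for c in config.outcome_covariates
                   if cohort.df[c].nunique() > 1]
            results["naive"] = naive_ever_treated_cox(cohort, adj)
        else:
            log.warning("no deaths in cohort; naive comparator skipped")
            results["naive"] = None

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "versions": {"obmatch": __version__,
                         "numpy": np.__version__, "pandas": pd.__version__,
                         "python": platform.python_version()},
            "counts": {"cohort": len(cohort), "pairs": len(matched.pairs),
                       "unmatched_treated": len(matched.unmatched_treated)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        results["manifest"] = manifest
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
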