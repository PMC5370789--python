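"""Synthetic dialysis-registry generator.

Emulates an incident-dialysis claims cohort in which kidney
transplantation is a time-dependent, confounded treatment: younger,
less comorbid patients receive a graft sooner, and transplantation
multiplies the subsequent death and cardiac-event hazards by a
proportional factor.  Event times are built by the piecewise-exponential
construction: each subject carries a constant covariate-specific hazard
that jumps by ``exp(theta)`` at the (latent) transplant time, and the
unit-exponential cumulative-hazard equation is inverted across the jump.

All times are reported in whole days since dialysis initiation;
day-level ties are therefore common, as in real claims data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import COMORBIDITY_COLUMNS, CohortTable, compute_cci

#: Reference covariate profile at which the baseline hazard scales apply:
#: a 50-year-old female HD patient with national insurance and no comorbidity.
_REFERENCE_AGE = 50.0

#: Marginal covariate distribution of the simulated registry.
DEFAULT_COVARIATE_DIST = {
    "age_mean": 55.0, "age_sd": 13.0, "age_min": 18, "age_max": 90,
    "p_male": 0.60, "p_pd": 0.25, "p_medical_aid": 0.13,
    "prevalence": {
        "dm": 0.35, "mi": 0.05, "chf": 0.15, "pvd": 0.05, "cvd": 0.10,
        "copd": 0.05, "pud": 0.10, "liver": 0.10, "cancer": 0.05,
    },
}

#: Log-hazard coefficients of the transplant (treatment) hazard: younger,
#: less comorbid, nationally insured patients are transplanted sooner.
DEFAULT_ALPHA = {
    "age": -0.13, "sex": 0.15, "modality": 0.30, "insurance": -1.00,
    "dm": -0.80, "mi": -0.80, "chf": -0.80, "pvd": -0.80, "cvd": -0.80,
    "copd": -0.80, "pud": -0.60, "liver": -0.60, "cancer": -1.20,
}

#: Log-hazard coefficients of the death hazard on baseline covariates.
DEFAULT_GAMMA = {
    "age": 0.05, "sex": 0.10, "modality": 0.00, "insurance": 0.30,
    "dm": 0.50, "mi": 0.40, "chf": 0.50, "pvd": 0.30, "cvd": 0.50,
    "copd": 0.30, "pud": 0.10, "liver": 0.30, "cancer": 0.80,
}


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic registry.

    Hazard scales are per day and apply at the reference profile
    (age 50, female, HD, NHI, no comorbidity); covariate effects act
    multiplicatively through ``exp(coef' x)`` with age centered at 50.
    ``theta_death`` / ``theta_mace`` are log hazard ratios of the
    time-varying treated state on the respective event hazards.
    """

    n: int = 5000
    seed: int = 0
    covariate_dist: dict = field(default_factory=lambda: _copy_nested(DEFAULT_COVARIATE_DIST))
    alpha: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    lambda_tx: float = 4.0e-4
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    theta_death: float = float(np.log(0.5))
    theta_mace: float = float(np.log(0.5))
    lambda_death: float = 2.5e-4
    lambda_mace: float = 1.5e-4
    admin_censor_window: float = 1825.0
    keep_latent: bool = False  # stash continuous latent times in meta

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size n must be >= 2")
        for name in ("lambda_tx", "lambda_death", "lambda_mace", "admin_censor_window"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v}")
        for name in ("theta_death", "theta_mace"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for coefs in (self.alpha, self.gamma):
            if not all(np.isfinite(list(coefs.values()))):
                raise ValueError("hazard coefficients must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


def _copy_nested(d: dict) -> dict:
    return {k: dict(v) if isinstance(v, dict) else v for k, v in d.items()}


def null_config(**overrides) -> SimulationConfig:
    """A no-confounding, no-treatment-effect scenario (all alpha = 0,
    theta_death = theta_mace = 0); useful for calibration checks."""
    cfg = SimulationConfig(**overrides)
    cfg.alpha = {k: 0.0 for k in cfg.alpha}
    cfg.theta_death = 0.0
    cfg.theta_mace = 0.0
    return cfg


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    cd = cfg.covariate_dist
    n = cfg.n
    age = rng.normal(cd["age_mean"], cd["age_sd"], n)
    age = np.clip(np.round(age), cd["age_min"], cd["age_max"]).astype(int)
    sex = np.where(rng.random(n) < cd["p_male"], "M", "F")
    modality = np.where(rng.random(n) < cd["p_pd"], "PD", "HD")
    insurance = np.where(rng.random(n) < cd["p_medical_aid"], "MedicalAid", "NHI")
    df = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": age, "sex": sex, "modality": modality, "insurance": insurance,
    })
    for flag in COMORBIDITY_COLUMNS:
        df[flag] = (rng.random(n) < cd["prevalence"][flag]).astype(int)
    df["cci"] = compute_cci(df[COMORBIDITY_COLUMNS].to_numpy(), df["age"].to_numpy())
    return df


def _linear_predictor(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    """coef' x with age centered at the reference and categories coded
    M/PD/MedicalAid = 1."""
    lp = np.zeros(len(df))
    for name, beta in coefs.items():
        if beta == 0.0:
            continue
        if name == "age":
            x = df["age"].to_numpy(float) - _REFERENCE_AGE
        elif name == "sex":
            x = (df["sex"] == "M").to_numpy(float)
        elif name == "modality":
            x = (df["modality"] == "PD").to_numpy(float)
        elif name == "insurance":
            x = (df["insurance"] == "MedicalAid").to_numpy(float)
        else:
            x = df[name].to_numpy(float)
        lp += beta * x
    return lp


def _piecewise_event_time(rate0: np.ndarray, t_switch: np.ndarray, theta: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Invert the cumulative hazard of a rate that jumps by exp(theta)
    at ``t_switch``: H(t) = rate0*t for t <= t_switch, then continues at
    slope rate0*exp(theta)."""
    e = rng.exponential(1.0, len(rate0))
    t_naive = e / rate0
    before = t_naive <= t_switch
    rate1 = rate0 * np.exp(theta)
    t_after = t_switch + (e - rate0 * t_switch) / rate1
    return np.where(before, t_naive, t_after)


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate a synthetic registry cohort.

    Transplant times follow an exponential hazard
    ``lambda_tx * exp(alpha' x)``; death and cardiac-event times follow
    piecewise-exponential hazards ``lambda * exp(gamma' x + theta Z(t))``
    where ``Z(t)`` switches on at the latent transplant time; censoring
    is uniform on ``(0, admin_censor_window]``.  A transplant is observed
    only if it precedes both death and censoring.  Deterministic under a
    fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    df = _draw_covariates(config, rng)

    rate_tx = config.lambda_tx * np.exp(_linear_predictor(df, config.alpha))
    rate_death = config.lambda_death * np.exp(_linear_predictor(df, config.gamma))
    rate_mace = config.lambda_mace * np.exp(_linear_predictor(df, config.gamma))
    if not (np.isfinite(rate_tx).all() and np.isfinite(rate_death).all() and np.isfinite(rate_mace).all()):
        raise ValueError("non-finite hazards; check coefficient magnitudes")

    t_tx = rng.exponential(1.0, config.n) / rate_tx
    t_death = _piecewise_event_time(rate_death, t_tx, config.theta_death, rng)
    t_mace = _piecewise_event_time(rate_mace, t_tx, config.theta_mace, rng)
    t_cens = rng.uniform(0.0, config.admin_censor_window, config.n)

    # whole-day grid (ceil, so every time is >= 1 day)
    d_tx = np.ceil(t_tx).astype(int)
    d_death = np.ceil(t_death).astype(int)
    d_mace = np.ceil(t_mace).astype(int)
    d_cens = np.maximum(np.ceil(t_cens).astype(int), 1)

    tx_observed = (t_tx < t_death) & (t_tx < t_cens)
    # rounding can collapse a continuous-time transplant onto the terminal
    # day; push the terminal time one day out to keep tx strictly first
    d_death = np.where(tx_observed & (d_death <= d_tx), d_tx + 1, d_death)
    d_cens = np.where(tx_observed & (d_cens <= d_tx), d_tx + 1, d_cens)

    death_observed = d_death <= d_cens
    mace_observed = (t_mace < t_death) & (t_mace < t_cens)

    df["tx_time"] = np.where(tx_observed, d_tx, np.nan)
    df["death_time"] = np.where(death_observed, d_death, np.nan)
    df["mace_time"] = np.where(mace_observed, d_mace, np.nan)
    df["censor_time"] = d_cens
    meta = {"config": config.to_dict()}
    if config.keep_latent:
        meta["latent"] = pd.DataFrame(
            {"t_tx": t_tx, "t_death": t_death, "t_mace": t_mace, "t_cens": t_cens})
    return CohortTable(df, meta=meta)
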