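"""Time-dependent propensity: the hazard of receiving transplantation.

The propensity for a time-dependent treatment is the treatment hazard
``h_m(t) = h0(t) exp(beta' x_m)`` estimated by a Cox model for
time-to-transplant, with death and administrative censoring treated as
censoring of the treatment process.  With time-fixed covariates the
linear predictor ``beta' x`` is constant over time for each subject,
and within a risk set at a common time the baseline hazard is a shared
factor, so matching on the linear predictor is equivalent to matching
on the hazard itself.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import PROPENSITY_COVARIATES, CohortTable, design_matrix, observed_followup
from .cox import CoxResult, fit_cox_newton


def _as_frame(cohort) -> pd.DataFrame:
    return cohort.df if isinstance(cohort, CohortTable) else cohort


class TreatmentHazardModel(BaseEstimator):
    """Cox model of the transplant hazard on baseline covariates.

    Parameters
    ----------
    covariates : list of str
        Cohort columns entering the model (default: age, sex, modality,
        insurance, the nine comorbidity flags, and the Charlson index).
    ties : {"breslow", "efron"}
        Tied-transplant-day handling.

    Attributes
    ----------
    covariate_names_ : list of str
    coef_ : ndarray — log-hazard coefficients.
    se_ : ndarray — Wald standard errors.
    loglik_ : float — partial log-likelihood at the optimum.
    converged_ : bool
    n_events_ : int — number of observed transplants.
    """

    def __init__(self, covariates=None, ties="breslow", max_iter=50, tol=1e-8):
        self.covariates = covariates
        self.ties = ties
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, cohort, y=None) -> "TreatmentHazardModel":
        df = _as_frame(cohort)
        names = list(self.covariates) if self.covariates is not None else list(PROPENSITY_COVARIATES)
        X = design_matrix(df, names)
        treated = df["tx_time"].notna().to_numpy()
        if treated.sum() == 0:
            raise ValueError("no transplant events in cohort; cannot estimate treatment hazard")
        # time to transplant; death/censoring censor the treatment process
        time = np.where(treated, df["tx_time"].to_numpy(float), observed_followup(df).to_numpy(float))
        res = fit_cox_newton(time, treated, X.to_numpy(), names=names,
                             ties=self.ties, max_iter=self.max_iter, tol=self.tol)
        self.result_: CoxResult = res
        self.covariate_names_ = list(names)
        self.coef_ = res.beta
        self.se_ = res.se
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.n_events_ = res.n_events
        return self

    def score_samples(self, cohort) -> np.ndarray:
        """Linear predictor ``beta' x`` per subject (the matching score)."""
        df = _as_frame(cohort)
        X = design_matrix(df, self.covariate_names_)
        return X.to_numpy() @ self.coef_

    def summary_dict(self) -> dict:
        res = self.result_
        ci = res.ci95
        return {
            "covariates": [
                {"name": nm, "beta": float(b), "se": float(s), "hr": float(h),
                 "ci95_low": float(lo), "ci95_high": float(hi), "p": float(p)}
                for nm, b, s, h, (lo, hi), p in zip(
                    res.names, res.beta, res.se, res.hr, ci, res.p_values)
            ],
            "loglik": res.loglik,
            "n_events": res.n_events,
            "ties": res.ties,
            "converged": res.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def fit_treatment_hazard(cohort, covariate_names=None, ties="breslow") -> TreatmentHazardModel:
    """Fit the transplant-hazard (propensity) model on a cohort."""
    return TreatmentHazardModel(covariates=covariate_names, ties=ties).fit(cohort)


def propensity_score(model: TreatmentHazardModel, subject) -> float:
    """Matching score for one subject (a cohort row or one-row frame)."""
    if isinstance(subject, pd.Series):
        subject = subject.to_frame().T
    return float(model.score_samples(subject)[0])
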