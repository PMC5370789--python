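"""Newton–Raphson solver for the Cox proportional-hazards partial likelihood.

Right-censored data with time-fixed covariates; ties handled by the
Breslow approximation by default (day-resolution claims data tie
heavily) with Efron's correction available.  Iterations stop when the
score (gradient) norm falls below tolerance; step-halving guards the
ascent.  Covariates are standardized internally for conditioning and
the fit is reported on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

_BETA_CAP = 10.0  # |beta| beyond this on the standardized scale flags separation


@dataclass
class CoxResult:
    """Maximum partial-likelihood fit."""

    names: list
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    converged: bool
    score_norm: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        with np.errstate(over="ignore"):  # capped fits have huge SEs
            lo = np.exp(self.beta - 1.959963984540054 * self.se)
            hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def wald_block_test(self, idx) -> tuple[float, int, float]:
        """Wald chi-square that a block of coefficients is zero."""
        idx = np.atleast_1d(idx)
        b = self.beta[idx]
        v = self.cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(v, b))
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))


def _loglik_parts_breslow(beta, time, event, X):
    """Breslow partial log-likelihood, gradient and negative Hessian.

    Arrays must be sorted by ascending time; risk-set sums are suffix
    cumulative sums taken at the start of each tied-time block.
    """
    n, p = X.shape
    eta = np.clip(X @ beta, -500, 500)
    w = np.exp(eta)
    wX = X * w[:, None]

    starts = np.flatnonzero(np.r_[True, time[1:] != time[:-1]])
    # suffix sums over the risk set at each distinct time
    S0 = np.cumsum(w[::-1])[::-1][starts]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1][starts]
    outer = np.einsum("ni,nj->nij", X, wX)
    S2 = np.cumsum(outer[::-1], axis=0)[::-1][starts]

    ev = event.astype(float)
    d = np.add.reduceat(ev, starts)
    sum_eta_ev = np.add.reduceat(eta * ev, starts)
    sum_X_ev = np.add.reduceat(X * ev[:, None], starts, axis=0)

    k = d > 0
    dk, S0k, S1k, S2k = d[k], S0[k], S1[k], S2[k]
    mu = S1k / S0k[:, None]
    loglik = float(sum_eta_ev[k].sum() - (dk * np.log(S0k)).sum())
    grad = sum_X_ev[k].sum(axis=0) - (dk[:, None] * mu).sum(axis=0)
    info = (np.einsum("k,kij->ij", dk, S2k / S0k[:, None, None])
            - np.einsum("k,ki,kj->ij", dk, mu, mu))
    return loglik, grad, info


def _loglik_parts_efron(beta, time, event, X):
    """Efron-tie version; per-block Python loop (optional path)."""
    n, p = X.shape
    eta = np.clip(X @ beta, -500, 500)
    w = np.exp(eta)
    wX = X * w[:, None]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    order = np.argsort(-time, kind="stable")
    td, ed, Xd, wd_, wXd, etad = (time[order], event[order], X[order],
                                  w[order], wX[order], eta[order])
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        t = td[i]
        while j < n and td[j] == t:
            j += 1
        block = slice(i, j)
        S0 += wd_[block].sum()
        S1 += wXd[block].sum(axis=0)
        S2 += Xd[block].T @ wXd[block]
        ev = ed[block]
        d = int(ev.sum())
        if d > 0:
            Xe = Xd[block][ev]
            loglik += etad[block][ev].sum()
            grad += Xe.sum(axis=0)
            tied_w = wd_[block][ev].sum()
            tied_S1 = wXd[block][ev].sum(axis=0)
            tied_S2 = Xe.T @ wXd[block][ev]
            for r in range(d):
                f = r / d
                s0 = S0 - f * tied_w
                s1 = S1 - f * tied_S1
                s2 = S2 - f * tied_S2
                loglik -= np.log(s0)
                mu = s1 / s0
                grad -= mu
                info += s2 / s0 - np.outer(mu, mu)
        i = j
    return loglik, grad, info


def _loglik_parts(beta, time, event, X, ties):
    if ties == "breslow":
        return _loglik_parts_breslow(beta, time, event, X)
    return _loglik_parts_efron(beta, time, event, X)


def score_residuals(beta, time, event, X):
    """Per-subject Cox score residuals at ``beta`` (Breslow convention).

    U_i = δ_i (x_i − μ(t_i)) − e^{η_i} Σ_{t_k ≤ t_i} (d_k/S0_k)(x_i − μ_k),
    the building block of the clustered sandwich variance.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(time, kind="stable")
    t, e, Xs = time[order], event[order], X[order]
    eta = np.clip(Xs @ beta, -500, 500)
    w = np.exp(eta)
    wX = Xs * w[:, None]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    sizes = np.diff(np.r_[starts, len(t)])
    S0 = np.cumsum(w[::-1])[::-1][starts]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1][starts]
    mu = S1 / S0[:, None]
    d = np.add.reduceat(e.astype(float), starts)
    a = d / S0                       # hazard increments at each time
    cumA = np.cumsum(a)
    cumB = np.cumsum(a[:, None] * mu, axis=0)
    block = np.repeat(np.arange(len(starts)), sizes)
    Ai = cumA[block]
    Bi = cumB[block]
    U = (e[:, None] * (Xs - mu[block])
         - w[:, None] * (Xs * Ai[:, None] - Bi))
    out = np.empty_like(U)
    out[order] = U
    return out


def clustered_covariance(result: "CoxResult", time, event, X, clusters) -> np.ndarray:
    """Sandwich covariance with scores summed within clusters (e.g.
    matched pairs).  Breslow score residuals are used regardless of the
    tie method (the usual approximation)."""
    U = score_residuals(result.beta, time, event, X)
    clusters = np.asarray(clusters)
    labels, idx = np.unique(clusters, return_inverse=True)
    G = np.zeros((len(labels), U.shape[1]))
    np.add.at(G, idx, U)
    meat = G.T @ G
    return result.cov @ meat @ result.cov


def fit_cox_newton(time, event, X, names=None, ties="breslow",
                   max_iter=50, tol=1e-8) -> CoxResult:
    """Fit a Cox model by Newton ascent of the partial likelihood.

    Parameters
    ----------
    time, event : array-like, shape (n,)
        Follow-up times and binary event indicators.
    X : array-like, shape (n, p)
        Time-fixed covariates.
    ties : {"breslow", "efron"}
        Tied-event handling.
    tol : float
        Stop when the gradient norm drops below this.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{k}" for k in range(p)]
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown ties method {ties!r}")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events; cannot fit a Cox model")
    const = X.std(axis=0) == 0
    if const.any():
        bad = [names[k] for k in np.flatnonzero(const)]
        raise ValueError(f"constant covariate(s): {bad}")

    # standardize for conditioning; map back afterwards
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    Xs = (X - center) / scale

    order = np.argsort(time, kind="stable")
    ts, es, Xo = time[order], event[order], Xs[order]

    beta = np.zeros(p)
    loglik, grad, info = _loglik_parts(beta, ts, es, Xo, ties)
    loglik_null = loglik
    converged = False
    separated = False
    for _ in range(max_iter):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.isfinite(step).all():
            # near-singular information (e.g. an almost-collinear
            # covariate): fall back to a lightly ridged solve
            ridge = 1e-10 * np.trace(info) / p
            step = np.linalg.solve(info + ridge * np.eye(p), grad)
        new_beta = beta + step
        new_ll, new_grad, new_info = _loglik_parts(new_beta, ts, es, Xo, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < loglik) and halvings < 20:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _loglik_parts(new_beta, ts, es, Xo, ties)
            halvings += 1
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if np.abs(beta).max() > _BETA_CAP:
            separated = True
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            loglik, grad, info = _loglik_parts(beta, ts, es, Xo, ties)
            break
    gnorm = float(np.linalg.norm(grad))
    if np.abs(beta).max() > _BETA_CAP:
        # the likelihood can flatten out at a huge finite coefficient,
        # with a vanishing gradient well beyond any plausible effect
        separated = True
        beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
        loglik, grad, info = _loglik_parts(beta, ts, es, Xo, ties)
        gnorm = float(np.linalg.norm(grad))
    if gnorm < tol and not separated:
        converged = True
    if separated:
        warnings.warn(
            "monotone partial likelihood (a covariate separates treated from "
            "untreated); coefficient capped", stacklevel=2)

    cov_s = np.linalg.pinv(info)
    # back-transform to the original covariate scale
    beta_orig = beta / scale
    D = np.diag(1.0 / scale)
    cov = D @ cov_s @ D
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxResult(
        names=list(names), beta=beta_orig, se=se, cov=cov,
        loglik=float(loglik), loglik_null=float(loglik_null),
        n=n, n_events=n_events, ties=ties,
        converged=bool(converged and not separated), score_norm=gnorm)
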