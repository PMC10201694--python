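"""Semiparametric proportional-hazards mixture cure model, fitted by EM.

Population survival decomposes as

    S_pop(t | X, Z) = pi(Z) * S_u(t | X) + 1 - pi(Z)

where pi(Z) = logistic(b'Z) is the probability of being *uncured*
(susceptible), and the uncured ("latency") survival S_u follows a Cox PH
model with nonparametric baseline, S_u(t|X) = exp(-H0(t) * exp(beta'X)).

EM treats the latent uncured indicator v_i as missing data:

* E-step: E[v_i] = 1 for deaths; for censored subjects
  pi_i S_u(t_i) / (1 - pi_i + pi_i S_u(t_i)). Under the zero-tail
  constraint S_u is 0 beyond the largest event time, so subjects censored
  after it are classified as cured.
* M-step: weighted logistic regression of E[v] on Z for b; an
  E[v]-weighted Breslow partial likelihood for beta (weights enter the risk
  sets, deaths count once); Breslow baseline update for H0.

The observed-data log-likelihood is nondecreasing across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from ._cox import breslow_increments, cox_newton, step_eval
from .cohort import Cohort, CohortError


@dataclass
class IncidenceModel:
    """Logistic model for the uncured probability pi(Z)."""

    names: list[str]  # covariates, without the intercept
    coef: np.ndarray  # [intercept, *names]
    se: np.ndarray | None = None

    def linear_predictor(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return self.coef[0] + Z @ self.coef[1:]

    def uncured_probability(self, Z: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(Z))


@dataclass
class LatencyModel:
    """PH model for the uncured with a Breslow step baseline hazard."""

    names: list[str]
    coef: np.ndarray
    baseline_times: np.ndarray  # distinct event times
    baseline_increments: np.ndarray  # dH0 at those times
    zero_tail: bool = True
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.baseline_cum = np.cumsum(self.baseline_increments)

    @property
    def last_event_time(self) -> float:
        return float(self.baseline_times[-1])

    def baseline_cum_hazard(self, t) -> np.ndarray:
        return step_eval(self.baseline_times, self.baseline_cum, t)

    def cum_hazard(self, X, t) -> np.ndarray:
        """Subject cumulative hazard H_i(t) = H0(t) * exp(beta'X)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.baseline_cum_hazard(t) * np.exp(X @ self.coef)

    def uncured_survival(self, X, t) -> np.ndarray:
        s = np.exp(-self.cum_hazard(X, t))
        if self.zero_tail:
            t_arr = np.atleast_1d(np.asarray(t, dtype=float))
            s = np.where(t_arr > self.last_event_time + 1e-12, 0.0, s)
        return s


@dataclass
class CureFit:
    """Fitted mixture cure model: incidence + latency + EM bookkeeping."""

    incidence: IncidenceModel
    latency: LatencyModel
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    posteriors: np.ndarray  # per-subject E[v_i]
    flags: list[str] = field(default_factory=list)

    model_name = "cure_ph"

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def n_parameters(self) -> int:
        return len(self.incidence.coef) + len(self.latency.coef)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "incidence": {
                "names": ["intercept", *self.incidence.names],
                "coef": self.incidence.coef.tolist(),
                "se": None if self.incidence.se is None else self.incidence.se.tolist(),
            },
            "latency": {
                "names": self.latency.names,
                "coef": self.latency.coef.tolist(),
                "se": None if self.latency.se is None else self.latency.se.tolist(),
                "baseline_times": self.latency.baseline_times.tolist(),
                "baseline_increments": self.latency.baseline_increments.tolist(),
                "zero_tail": self.latency.zero_tail,
            },
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "flags": self.flags,
        }


# -- pieces ------------------------------------------------------------------


def e_step_uncured(pi: np.ndarray, s_uncured: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Posterior uncured probability E[v_i | data, params].

    Deaths are uncured by definition; for censored subjects Bayes' rule on
    cured-vs-uncured survival. 0/0 (pi = 0) resolves to 0.
    """
    num = pi * s_uncured
    den = 1.0 - pi + num
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(den > 0, num / den, 0.0)
    return np.where(event == 1, 1.0, post)


def _weighted_logistic(Zd: np.ndarray, target: np.ndarray, start=None):
    """Fractional-response logistic fit (GLM binomial); returns coefficients."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(target, Zd, family=sm.families.Binomial())
        res = model.fit(start_params=start, maxiter=200)
    return np.asarray(res.params, dtype=float)


def _observed_loglik(pi, event, time, eta_lat, latency: LatencyModel) -> float:
    H0 = latency.baseline_cum_hazard(time)
    Hi = H0 * np.exp(eta_lat)
    s_u = np.exp(-Hi)
    if latency.zero_tail:
        s_u = np.where(time > latency.last_event_time + 1e-12, 0.0, s_u)
    bl_t = latency.baseline_times
    idx = np.searchsorted(bl_t, time)
    safe = np.minimum(idx, len(bl_t) - 1)
    at_event = (idx < len(bl_t)) & np.isclose(bl_t[safe], time)
    dH = np.zeros_like(time)
    dH[at_event] = latency.baseline_increments[safe[at_event]]
    with np.errstate(divide="ignore"):
        death_ll = np.log(pi) + np.log(dH) + eta_lat - Hi
        cens_ll = np.log(np.maximum(1.0 - pi + pi * s_u, 1e-300))
    return float(np.where(event == 1, death_ll, cens_ll).sum())


def _model_matrices(cohort: Cohort):
    z_names = list(cohort.schema.incidence)
    x_names = list(cohort.schema.latency)
    Z = cohort.covariate_matrix(z_names)
    X = cohort.covariate_matrix(x_names)
    if np.isnan(Z).any() or np.isnan(X).any():
        raise CohortError("model covariates contain missing values; impute first")
    return z_names, x_names, Z, X


# -- fitting -----------------------------------------------------------------


def fit_mixture_cure_ph(
    cohort: Cohort,
    tol: float = 1e-7,
    max_iter: int = 500,
    zero_tail: bool = True,
) -> CureFit:
    """EM fit of the semiparametric PH mixture cure model.

    Initialization: b from a logistic regression of the event indicator on
    Z, beta from a plain Cox fit. Convergence: relative change of the
    observed-data log-likelihood below ``tol``. A non-converged fit is
    returned with ``converged=False`` and a flag rather than raised.
    """
    if cohort.n_events < 1:
        raise CohortError("model fitting requires at least one event")
    z_names, x_names, Z, X = _model_matrices(cohort)
    time, event = cohort.time, cohort.event
    Zd = np.column_stack([np.ones(cohort.n), Z])
    flags: list[str] = []

    b = _weighted_logistic(Zd, event.astype(float))
    cox0 = cox_newton(time, event, X)
    beta = cox0.beta
    bl_t, bl_inc = breslow_increments(time, event, X, beta)

    trace: list[float] = []
    converged = False
    post = event.astype(float)
    it = 0
    for it in range(1, max_iter + 1):
        latency = LatencyModel(x_names, beta, bl_t, bl_inc, zero_tail=zero_tail)
        pi = expit(Zd @ b)
        eta_lat = X @ beta
        s_u = np.exp(-latency.baseline_cum_hazard(time) * np.exp(eta_lat))
        if zero_tail:
            s_u = np.where(time > latency.last_event_time + 1e-12, 0.0, s_u)
        post = e_step_uncured(pi, s_u, event)

        ll = _observed_loglik(pi, event, time, eta_lat, latency)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1.0 + abs(trace[-1])):
            converged = True
            break

        b = _weighted_logistic(Zd, post, start=b)
        if np.abs(b).max() > 25:
            flags.append("possible complete separation in the incidence part")
        cox = cox_newton(time, event, X, risk_weight=post, beta0=beta)
        beta = cox.beta
        bl_t, bl_inc = breslow_increments(time, event, X, beta, risk_weight=post)

    if not converged:
        flags.append(f"EM did not converge within {max_iter} iterations")
        warnings.warn(flags[-1])
        # refresh posteriors so they are consistent with the returned params
        latency = LatencyModel(x_names, beta, bl_t, bl_inc, zero_tail=zero_tail)
        pi = expit(Zd @ b)
        eta_lat = X @ beta
        s_u = np.exp(-latency.baseline_cum_hazard(time) * np.exp(eta_lat))
        if zero_tail:
            s_u = np.where(time > latency.last_event_time + 1e-12, 0.0, s_u)
        post = e_step_uncured(pi, s_u, event)
        trace.append(_observed_loglik(pi, event, time, eta_lat, latency))

    incidence = IncidenceModel(z_names, b)
    latency = LatencyModel(x_names, beta, bl_t, bl_inc, zero_tail=zero_tail)
    return CureFit(
        incidence=incidence,
        latency=latency,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        posteriors=post,
        flags=sorted(set(flags)),
    )


# -- predictions -------------------------------------------------------------


def _row_to_array(fit_names: list[str], covariates) -> np.ndarray:
    if isinstance(covariates, dict):
        return np.array([float(covariates[c]) for c in fit_names])
    if isinstance(covariates, pd.Series):
        return covariates[fit_names].to_numpy(dtype=float)
    return np.asarray(covariates, dtype=float)


def cure_probability(fit: CureFit, covariates) -> float:
    """1 - pi(Z): the probability of never experiencing the event."""
    z = _row_to_array(fit.incidence.names, covariates)
    return float(1.0 - fit.incidence.uncured_probability(z)[0])


def population_survival(fit: CureFit, covariates, t) -> np.ndarray:
    """S_pop(t|X,Z) = pi(Z) S_u(t|X) + 1 - pi(Z) (marginal over cure status)."""
    z = _row_to_array(fit.incidence.names, covariates)
    x = _row_to_array(fit.latency.names, covariates)
    pi = fit.incidence.uncured_probability(z)[0]
    s_u = fit.latency.uncured_survival(x, t)
    return pi * s_u + 1.0 - pi
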