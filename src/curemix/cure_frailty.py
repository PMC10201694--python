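"""Mixture cure model with subject-level gamma frailty, fitted by EM.

The incidence part is the same logistic model pi(Z) = logistic(theta'Z) for
the probability of being uncured. Conditional on being uncured (v = 1) and a
frailty w ~ Gamma(1/psi, psi) (mean 1, variance psi), the hazard is

    h(t | w, X, v=1) = w * h0(t) * exp(beta'X),

so the frailty-marginal uncured survival is (1 + psi * H(t))^(-1/psi) with
H(t) = H0(t) exp(beta'X), reducing to exp(-H) as psi -> 0.

EM exploits gamma conjugacy: given the observed data and uncured status, the
frailty posterior is Gamma(1/psi + delta, psi / (1 + psi H)), so the E-step
needs only E[v], E[w | uncured] and E[log w | uncured] in closed form. The
M-step updates theta by weighted logistic regression and (beta, H0) by a
partial likelihood in which subject j carries risk multiplier
E[v_j] E[w_j | uncured]. The frailty variance is then updated by directly
maximizing the observed log-likelihood in psi with the other parameters
held fixed (an ECME-style conditional maximization): the classical
expected-gamma-score EM update moves psi extremely slowly along the flat
psi ridge and can stall, while the conditional maximization preserves
monotonicity and converges reliably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, expit, gammaln
from scipy.stats import chi2

from ._cox import breslow_increments, cox_newton
from .cohort import Cohort, CohortError
from .cure_ph import (
    CureFit,
    IncidenceModel,
    LatencyModel,
    _model_matrices,
    _weighted_logistic,
    e_step_uncured,
)

PSI_MIN = 1e-8
PSI_MAX = 50.0


# -- frailty primitives ------------------------------------------------------


def gamma_frailty_density(w, psi: float) -> np.ndarray:
    """Gamma(1/psi, psi) density (mean 1, variance psi) at w > 0."""
    if psi <= 0:
        raise ValueError("psi must be positive")
    w = np.asarray(w, dtype=float)
    a = 1.0 / psi
    return np.exp((a - 1.0) * np.log(w) - w / psi - gammaln(a) - a * np.log(psi))


def marginal_uncured_survival(H, psi: float) -> np.ndarray:
    """Frailty-marginal uncured survival: E_w[exp(-wH)] = (1+psi H)^(-1/psi).

    Continuous at psi = 0, where it equals exp(-H).
    """
    H = np.asarray(H, dtype=float)
    if psi <= 0:
        return np.exp(-H)
    return (1.0 + psi * H) ** (-1.0 / psi)


def frailty_posterior_moments(psi: float, H, delta) -> tuple[np.ndarray, np.ndarray]:
    """E[w | uncured, data] and E[log w | uncured, data].

    The posterior is Gamma(1/psi + delta, psi/(1 + psi H)): mean
    (1 + psi*delta)/(1 + psi*H), mean-log digamma(1/psi + delta) +
    log(psi/(1 + psi H)). For psi <= 0 the frailty is degenerate at 1.
    """
    H = np.asarray(H, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if psi <= 0:
        return np.ones_like(H), np.zeros_like(H)
    ew = (1.0 + psi * delta) / (1.0 + psi * H)
    elog = digamma(1.0 / psi + delta) + np.log(psi / (1.0 + psi * H))
    return ew, elog


def complete_data_loglik(params, cohort: Cohort, v, w) -> float:
    """Log complete-data likelihood sum_i log L_{i,c} at given latent (v, w).

    ``params`` is (theta, beta, baseline, psi) with theta ordered
    [intercept, *incidence covariates], baseline a (times, increments) pair.
    A death with v = 0 contradicts cure and contributes -inf (flagged).
    """
    theta, beta, (bl_t, bl_inc), psi = params
    z_names, x_names, Z, X = _model_matrices(cohort)
    time, event = cohort.time, cohort.event
    v = np.asarray(v, dtype=int)
    w = np.asarray(w, dtype=float)
    pi = expit(theta[0] + Z @ np.asarray(theta[1:], dtype=float))
    bl_t = np.asarray(bl_t, dtype=float)
    bl_inc = np.asarray(bl_inc, dtype=float)
    # H0(t) is right-continuous and includes the increment at t itself,
    # matching the Breslow convention used by the fitters
    from ._cox import step_eval

    H0 = step_eval(bl_t, np.cumsum(bl_inc), time)
    idx = np.searchsorted(bl_t, time)
    safe = np.minimum(idx, len(bl_t) - 1)
    at_event = (idx < len(bl_t)) & np.isclose(bl_t[safe], time)
    h0 = np.zeros_like(time)
    h0[at_event] = bl_inc[safe[at_event]]
    eta = X @ np.asarray(beta, dtype=float)
    Hi = H0 * np.exp(eta)

    if np.any((event == 1) & (v == 0)):
        warnings.warn("death observed for a subject with v=0: -inf likelihood")
        return float("-inf")

    ll = np.where(v == 0, np.log(np.maximum(1.0 - pi, 1e-300)), 0.0).astype(float)
    unc = v == 1
    if unc.any():
        a = 1.0 / psi
        gw = (a - 1.0) * np.log(w[unc]) - w[unc] / psi - gammaln(a) - a * np.log(psi)
        haz = np.where(
            event[unc] == 1,
            np.log(np.maximum(w[unc] * h0[unc], 1e-300)) + eta[unc],
            0.0,
        )
        ll[unc] += np.log(np.maximum(pi[unc], 1e-300)) + gw + haz - w[unc] * Hi[unc]
    return float(ll.sum())


# -- fit container -----------------------------------------------------------


@dataclass
class FrailtyCureFit(CureFit):
    """Mixture cure frailty fit: CureFit plus the frailty variance psi."""

    psi: float = 0.0
    psi_se: float | None = None
    psi_ci: tuple[float, float] | None = None
    posterior_frailty: np.ndarray | None = None  # E[w_i | uncured, data]
    posterior_log_frailty: np.ndarray | None = None

    model_name = "cure_frailty"

    @property
    def n_parameters(self) -> int:
        return super().n_parameters + 1

    def to_dict(self) -> dict:
        out = super().to_dict()
        out["psi"] = self.psi
        out["psi_se"] = self.psi_se
        out["psi_ci"] = list(self.psi_ci) if self.psi_ci is not None else None
        return out


def _psi_em_score_update(c: float) -> float:
    """Classical EM update: solve log(a) - digamma(a) = -1 - c for a = 1/psi,
    where c is the posterior-weighted mean of E[log w] - E[w]. Kept for
    reference/tests; the fitter uses the direct conditional maximization
    below, because this update moves psi so slowly along the flat psi ridge
    that the fit can stall far from the optimum."""
    target = -1.0 - c
    if target <= 1e-12:
        return PSI_MIN
    f = lambda loga: loga - digamma(np.exp(loga)) - target
    lo, hi = np.log(1.0 / PSI_MAX), np.log(1.0 / PSI_MIN)
    if f(lo) < 0:  # even psi = PSI_MAX under-disperses
        return PSI_MAX
    if f(hi) > 0:
        return PSI_MIN
    loga = brentq(f, lo, hi, xtol=1e-12)
    return float(np.clip(1.0 / np.exp(loga), PSI_MIN, PSI_MAX))


def _psi_direct_update(pi, event, time, eta_lat, latency) -> float:
    """Conditional maximization of the observed log-likelihood in psi
    (ECME-style); monotone by construction and immune to the EM ridge crawl."""
    from scipy.optimize import minimize_scalar

    def neg(log_psi):
        return -_observed_loglik_frailty(pi, event, time, eta_lat, latency, float(np.exp(log_psi)))

    res = minimize_scalar(
        neg, bounds=(np.log(PSI_MIN), np.log(PSI_MAX)), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.clip(np.exp(res.x), PSI_MIN, PSI_MAX))


def _observed_loglik_frailty(pi, event, time, eta_lat, latency: LatencyModel, psi: float) -> float:
    H0 = latency.baseline_cum_hazard(time)
    Hi = H0 * np.exp(eta_lat)
    s_marg = marginal_uncured_survival(Hi, psi)
    if latency.zero_tail:
        s_marg = np.where(time > latency.last_event_time + 1e-12, 0.0, s_marg)
    bl_t = latency.baseline_times
    idx = np.searchsorted(bl_t, time)
    safe = np.minimum(idx, len(bl_t) - 1)
    at_event = (idx < len(bl_t)) & np.isclose(bl_t[safe], time)
    dH = np.zeros_like(time)
    dH[at_event] = latency.baseline_increments[safe[at_event]]
    with np.errstate(divide="ignore"):
        death_ll = (
            np.log(pi)
            + np.log(dH)
            + eta_lat
            - (1.0 / psi + 1.0) * np.log1p(psi * Hi)
        )
        cens_ll = np.log(np.maximum(1.0 - pi + pi * s_marg, 1e-300))
    return float(np.where(event == 1, death_ll, cens_ll).sum())


def fit_mixture_cure_frailty(
    cohort: Cohort,
    tol: float = 1e-7,
    max_iter: int = 500,
    zero_tail: bool = True,
    fix_psi: float | None = None,
    psi_init: float = 0.5,
) -> FrailtyCureFit:
    """EM fit of the gamma-frailty mixture cure model.

    ``fix_psi`` freezes the frailty variance (useful for profile likelihood
    and for the psi -> 0 equivalence with the non-frailty model). A psi
    estimate collapsing to the boundary degrades gracefully to the
    non-frailty model and is flagged.
    """
    if cohort.n_events < 1:
        raise CohortError("model fitting requires at least one event")
    z_names, x_names, Z, X = _model_matrices(cohort)
    time, event = cohort.time, cohort.event
    Zd = np.column_stack([np.ones(cohort.n), Z])
    flags: list[str] = []

    theta = _weighted_logistic(Zd, event.astype(float))
    cox0 = cox_newton(time, event, X)
    beta = cox0.beta
    bl_t, bl_inc = breslow_increments(time, event, X, beta)
    psi = float(np.clip(fix_psi if fix_psi is not None else psi_init, PSI_MIN, PSI_MAX))

    trace: list[float] = []
    converged = False
    post = event.astype(float)
    ew = np.ones(cohort.n)
    elog = np.zeros(cohort.n)
    it = 0
    for it in range(1, max_iter + 1):
        latency = LatencyModel(x_names, beta, bl_t, bl_inc, zero_tail=zero_tail)
        pi = expit(Zd @ theta)
        eta_lat = X @ beta
        Hi = latency.baseline_cum_hazard(time) * np.exp(eta_lat)
        s_marg = marginal_uncured_survival(Hi, psi)
        if zero_tail:
            s_marg = np.where(time > latency.last_event_time + 1e-12, 0.0, s_marg)
        post = e_step_uncured(pi, s_marg, event)
        ew, elog = frailty_posterior_moments(psi, Hi, event)

        ll = _observed_loglik_frailty(pi, event, time, eta_lat, latency, psi)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1.0 + abs(trace[-1])):
            converged = True
            break

        theta = _weighted_logistic(Zd, post, start=theta)
        if np.abs(theta).max() > 25:
            flags.append("possible complete separation in the incidence part")
        rw = post * ew
        cox = cox_newton(time, event, X, risk_weight=rw, beta0=beta)
        beta = cox.beta
        bl_t, bl_inc = breslow_increments(time, event, X, beta, risk_weight=rw)
        if fix_psi is None:
            latency = LatencyModel(x_names, beta, bl_t, bl_inc, zero_tail=zero_tail)
            pi = expit(Zd @ theta)
            eta_lat = X @ beta
            psi = _psi_direct_update(pi, event, time, eta_lat, latency)

    if not converged:
        flags.append(f"EM did not converge within {max_iter} iterations")
        warnings.warn(flags[-1])
        # refresh posteriors so they are consistent with the returned params
        latency = LatencyModel(x_names, beta, bl_t, bl_inc, zero_tail=zero_tail)
        pi = expit(Zd @ theta)
        eta_lat = X @ beta
        Hi = latency.baseline_cum_hazard(time) * np.exp(eta_lat)
        s_marg = marginal_uncured_survival(Hi, psi)
        if zero_tail:
            s_marg = np.where(time > latency.last_event_time + 1e-12, 0.0, s_marg)
        post = e_step_uncured(pi, s_marg, event)
        ew, elog = frailty_posterior_moments(psi, Hi, event)
        trace.append(_observed_loglik_frailty(pi, event, time, eta_lat, latency, psi))
    if fix_psi is None and psi <= 10 * PSI_MIN:
        flags.append("frailty variance collapsed to the boundary (psi ~ 0)")

    incidence = IncidenceModel(z_names, theta)
    latency = LatencyModel(x_names, beta, bl_t, bl_inc, zero_tail=zero_tail)
    return FrailtyCureFit(
        incidence=incidence,
        latency=latency,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        posteriors=post,
        flags=sorted(set(flags)),
        psi=psi,
        posterior_frailty=ew,
        posterior_log_frailty=elog,
    )


def population_survival_frailty(fit: FrailtyCureFit, covariates, t) -> np.ndarray:
    """pi(Z) (1 + psi H(t))^(-1/psi) + 1 - pi(Z)."""
    from .cure_ph import _row_to_array

    z = _row_to_array(fit.incidence.names, covariates)
    x = _row_to_array(fit.latency.names, covariates)
    pi = fit.incidence.uncured_probability(z)[0]
    H = fit.latency.cum_hazard(x, t)
    s = marginal_uncured_survival(H, fit.psi)
    if fit.latency.zero_tail:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        s = np.where(t_arr > fit.latency.last_event_time + 1e-12, 0.0, s)
    return pi * s + 1.0 - pi


def frailty_lr_test(frailty_fit: FrailtyCureFit, null_fit: "CureFit | FrailtyCureFit") -> dict:
    """Boundary-corrected likelihood-ratio test for psi = 0.

    Under the null the frailty variance sits on the parameter-space boundary,
    so the LR statistic is referred to a 50:50 mixture of chi2_0 and chi2_1.
    ``null_fit`` should be the same model fitted with psi fixed at ~0 (or the
    non-frailty mixture cure fit, whose likelihood is the psi -> 0 limit).
    """
    stat = max(0.0, 2.0 * (frailty_fit.loglik - null_fit.loglik))
    p = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return {"statistic": stat, "p_value": p}


def profile_psi_ci(
    cohort: Cohort,
    fit: FrailtyCureFit,
    level: float = 0.95,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[float, float]:
    """Profile-likelihood CI for psi: the set where the profile log-likelihood
    stays within chi2_{1,level}/2 of the maximum (boundary-truncated)."""
    cut = fit.loglik - 0.5 * chi2.ppf(level, df=1)

    def drop(psi_val: float) -> float:
        f = fit_mixture_cure_frailty(
            cohort, tol=tol, max_iter=max_iter, zero_tail=fit.latency.zero_tail, fix_psi=psi_val
        )
        return f.loglik - cut

    lo = PSI_MIN
    if drop(PSI_MIN) < 0:
        lo = brentq(drop, PSI_MIN, fit.psi, xtol=1e-4)
    hi = PSI_MAX
    if drop(PSI_MAX) < 0:
        hi = brentq(drop, fit.psi, PSI_MAX, xtol=1e-4)
    return float(lo), float(hi)
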