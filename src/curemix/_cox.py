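"""Weighted Cox partial likelihood with Breslow tie handling.

The EM algorithms for the mixture cure models profile out a nonparametric
baseline hazard and maximize, at each M-step, a partial likelihood in which
subjects carry *risk multipliers* that differ from their event weights:

* PH mixture cure: subject j enters every risk set scaled by its posterior
  uncured probability E[v_j]; deaths contribute with weight 1 (E[v]=1).
* frailty mixture cure: the risk multiplier is E[v_j]·E[w_j | uncured],
  the posterior expected frailty-scaled membership.

log PL(beta) = sum_deaths ew_i * x_i'beta
             - sum_k d_k * log( sum_{t_j >= t_k} rw_j * exp(x_j'beta) )

with d_k the event-weight total at the k-th distinct death time (Breslow
approximation for ties). The Breslow baseline increment at t_k is
d_k / S0(t_k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CoxResult:
    beta: np.ndarray
    loglik: float
    gradient: np.ndarray
    information: np.ndarray  # negative Hessian
    n_iter: int
    converged: bool


def _prepare(time, event, X, risk_weight, event_weight):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(time)
    rw = np.ones(n) if risk_weight is None else np.asarray(risk_weight, dtype=float)
    ew = np.ones(n) if event_weight is None else np.asarray(event_weight, dtype=float)
    order = np.argsort(time, kind="stable")
    return time[order], event[order], X[order], rw[order], ew[order]


def _sums(time, event, X, rw, ew, beta):
    """Per distinct death time: d_k, S0, S1, S2 and the numerator terms."""
    eta = X @ beta
    emax = eta.max() if len(eta) else 0.0
    w = rw * np.exp(eta - emax)
    # suffix (reverse cumulative) sums over subjects sorted by ascending time
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    c2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    death_mask = event == 1
    dt = time[death_mask]
    uniq, first_death_idx = np.unique(dt, return_index=True)
    # first subject index with time >= each distinct death time
    start = np.searchsorted(time, uniq, side="left")
    S0 = c0[start]
    S1 = c1[start]
    S2 = c2[start]

    dw = ew * death_mask
    # deaths are already time-sorted; sum event weights within tied death times
    d_k = np.add.reduceat(dw[death_mask], np.searchsorted(dt, uniq, side="left"))
    num_eta = float((dw * eta).sum())
    num_x = (dw[:, None] * X).sum(axis=0)
    loglik = num_eta - float((d_k * (np.log(S0) + emax)).sum())
    return uniq, d_k, S0, S1, S2, num_x, loglik, emax


def cox_loglik(beta, time, event, X, risk_weight=None, event_weight=None) -> float:
    time, event, X, rw, ew = _prepare(time, event, X, risk_weight, event_weight)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return _sums(time, event, X, rw, ew, beta)[6]


def cox_newton(
    time,
    event,
    X,
    risk_weight=None,
    event_weight=None,
    beta0=None,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> CoxResult:
    """Newton–Raphson maximizer of the weighted Breslow partial likelihood."""
    time, event, X, rw, ew = _prepare(time, event, X, risk_weight, event_weight)
    p = X.shape[1]
    if p == 0:
        return CoxResult(np.zeros(0), 0.0, np.zeros(0), np.zeros((0, 0)), 0, True)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll = -np.inf
    grad = np.zeros(p)
    info = np.eye(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, d_k, S0, S1, S2, num_x, ll_new, _emax = _sums(time, event, X, rw, ew, beta)
        mean = S1 / S0[:, None]
        grad = num_x - (d_k[:, None] * mean).sum(axis=0)
        info = np.einsum("k,kij->ij", d_k, S2 / S0[:, None, None]) - np.einsum(
            "k,ki,kj->ij", d_k, mean, mean
        )
        if ll_new < ll - 1e-12:  # step-halving fallback
            beta = 0.5 * (beta + beta_prev)
            continue
        if abs(ll_new - ll) < tol * (1.0 + abs(ll_new)) and np.abs(grad).max() < 1e-6:
            ll = ll_new
            converged = True
            break
        ll = ll_new
        beta_prev = beta
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # guard against overshoot in early iterations
        norm = np.abs(step).max()
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
    return CoxResult(beta, ll, grad, info, it, converged)


def breslow_increments(
    time, event, X, beta, risk_weight=None, event_weight=None
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow baseline hazard increments d_k / S0(t_k) at distinct death times."""
    time, event, X, rw, ew = _prepare(time, event, X, risk_weight, event_weight)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if X.shape[1] == 0:
        X = np.zeros((len(time), 0))
        beta = np.zeros(0)
    out = _sums(time, event, X, rw, ew, beta)
    uniq, d_k, S0, emax = out[0], out[1], out[2], out[7]
    # undo the exp-centering applied to the risk sums
    return uniq, d_k / S0 * np.exp(-emax)


def step_eval(step_times: np.ndarray, step_cum: np.ndarray, t) -> np.ndarray:
    """Evaluate a right-continuous step function (cumulative at step_times)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(step_times, t, side="right")
    out = np.where(idx > 0, step_cum[np.minimum(idx, len(step_cum)) - 1], 0.0)
    return out
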