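"""Nonparametric pre-model diagnostics.

Kaplan–Meier estimation (product-limit, deaths processed before censorings at
tied times), terminal-plateau measurement, the Maller–Zhou check for a cure
fraction / sufficient follow-up, and the ln(-ln S) graphical proportional-
hazards diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import norm

from .cohort import Cohort, CohortError


@dataclass
class KMCurve:
    """Product-limit estimate with at-risk/event/censoring counts per time."""

    times: np.ndarray  # distinct observed times, sorted
    survival: np.ndarray  # S(t) at those times (right-continuous)
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        return np.where(idx > 0, self.survival[np.maximum(idx - 1, 0)], 1.0)

    @property
    def last_event_time(self) -> float:
        has = self.n_events > 0
        return float(self.times[has][-1]) if has.any() else float("nan")

    @property
    def max_time(self) -> float:
        return float(self.times[-1])

    def greenwood_variance_at(self, t: float) -> float:
        """Greenwood's formula for Var[S_hat(t)]."""
        mask = (self.times <= t) & (self.n_events > 0)
        d = self.n_events[mask].astype(float)
        r = self.at_risk[mask].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = d / (r * (r - d))
        terms = terms[np.isfinite(terms)]
        s = float(self.survival_at(t)[0])
        return s * s * float(terms.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "censored": self.n_censored,
            }
        )


def kaplan_meier(cohort_or_times, event=None) -> KMCurve:
    """Kaplan–Meier estimate of a cohort (or raw time/event arrays)."""
    if isinstance(cohort_or_times, Cohort):
        time = cohort_or_times.time
        ev = cohort_or_times.event
    else:
        time = np.asarray(cohort_or_times, dtype=float)
        ev = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise CohortError("Kaplan-Meier requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=ev)

    uniq = np.unique(time)
    order = np.argsort(time, kind="stable")
    ts, es = time[order], ev[order]
    starts = np.searchsorted(ts, uniq, side="left")
    d = np.add.reduceat(es, starts)
    total = np.add.reduceat(np.ones_like(es), starts)
    at_risk = len(ts) - starts
    surv = kmf.survival_function_at_times(uniq).to_numpy()
    return KMCurve(
        times=uniq,
        survival=surv,
        at_risk=at_risk,
        n_events=d,
        n_censored=total - d,
    )


def plateau_length(curve: KMCurve) -> tuple[float, bool]:
    """Length of the terminal flat stretch of the KM curve.

    Returns (months from the last event time to the largest observed time,
    has_plateau). When the curve reaches zero (the largest time is an event)
    there are no long-term survivors and (0.0, False) is returned.
    """
    last_event = curve.last_event_time
    if np.isnan(last_event):
        return float(curve.max_time), True  # no events at all: flat from 0
    level = float(curve.survival_at(last_event)[0])
    if level <= 0.0 or curve.max_time <= last_event:
        return 0.0, False
    return float(curve.max_time - last_event), True


@dataclass
class MallerZhouResult:
    """Cure-fraction and sufficient-follow-up diagnostics from the KM tail.

    ``estimated_cure_fraction`` is S_KM at the largest event time t*;
    ``n_interval`` counts uncensored times in (2 t* - t_max, t*], whose
    scarcity signals insufficient follow-up; ``p_value`` is a one-sided
    Greenwood-variance normal test of a zero cure fraction.
    """

    estimated_cure_fraction: float
    se_cure_fraction: float
    p_value: float
    cure_detected: bool
    n_interval: int
    alpha_n: float  # n_interval / n
    p_sufficient_followup: float
    sufficient_followup: bool
    alpha: float


def maller_zhou_test(cohort: Cohort, alpha: float = 0.05) -> MallerZhouResult:
    """Nonparametric check for long-term survivors and follow-up adequacy.

    The cure fraction is estimated by the KM plateau level q_hat = S_KM(t*)
    at the largest *event* time t*; H0: no cure (q = 0) is tested one-sided
    with the Greenwood standard error. Follow-up adequacy uses N_n, the
    number of uncensored times in (2 t* - t_max, t*] with t_max the largest
    observed time: the approximate p-value (1 - N_n/n)^n is small when the
    interval is well populated, i.e. when events thin out well before
    follow-up ends.
    """
    if cohort.n_events < 1:
        raise CohortError("Maller-Zhou test requires at least one event")
    curve = kaplan_meier(cohort)
    t_star = curve.last_event_time
    t_max = curve.max_time
    qhat = float(curve.survival_at(t_star)[0])
    var = curve.greenwood_variance_at(t_star)
    se = float(np.sqrt(max(var, 0.0)))
    if qhat <= 0.0:
        p = 1.0
    elif se == 0.0:
        p = 0.0
    else:
        p = float(norm.sf(qhat / se))
    time, ev = cohort.time, cohort.event
    lo = 2.0 * t_star - t_max
    n_int = int(np.sum((ev == 1) & (time > lo) & (time <= t_star)))
    alpha_n = n_int / cohort.n
    p_suff = float((1.0 - alpha_n) ** cohort.n)
    return MallerZhouResult(
        estimated_cure_fraction=qhat,
        se_cure_fraction=se,
        p_value=p,
        cure_detected=bool(p < alpha and qhat > 0),
        n_interval=n_int,
        alpha_n=alpha_n,
        p_sufficient_followup=p_suff,
        sufficient_followup=bool(p_suff < alpha),
        alpha=alpha,
    )


@dataclass
class LogLogCheck:
    """Stratified ln(-ln S) curves and a descriptive parallelism diagnostic."""

    grid: np.ndarray  # common event times with 0 < S < 1 in every stratum
    curves: dict[object, np.ndarray]  # stratum level -> ln(-ln S) on the grid
    gap: np.ndarray  # level-1 minus level-0 curve
    gap_range: float  # max gap - min gap; near 0 <=> parallel <=> PH plausible
    gap_mean: float
    sign_change: bool  # crossing log-log curves: clear PH violation


def loglog_survival_check(cohort: Cohort, covariate: str, min_at_risk: int = 15) -> LogLogCheck:
    """ln(-ln S_KM(t)) per stratum of a binary covariate, on the common grid
    of event times where every stratum's survival lies strictly in (0, 1).

    Under proportional hazards the two curves differ by the constant log
    hazard ratio, so ``gap_range`` near zero supports PH; a sign change in
    the gap flags crossing hazards. Times at which any stratum has fewer
    than ``min_at_risk`` subjects still at risk are excluded — the KM tail
    there is dominated by a handful of subjects and the transform is pure
    noise. Strata with no events are omitted with a warning.
    """
    df = cohort.data
    if df[covariate].isna().any():
        raise CohortError(f"covariate {covariate!r} has missing values")
    curves: dict[object, KMCurve] = {}
    stratum_times: dict[object, np.ndarray] = {}
    for level in (0, 1):
        sub = df[df[covariate] == level]
        if len(sub) == 0 or sub["event"].sum() == 0:
            warnings.warn(f"stratum {covariate}={level} has no events; omitted")
            continue
        stratum_times[level] = sub["time"].to_numpy(float)
        curves[level] = kaplan_meier(
            stratum_times[level], sub["event"].to_numpy(int)
        )
    event_times = np.unique(df.loc[df["event"] == 1, "time"].to_numpy(float))
    grid = []
    for t in event_times:
        vals = [float(c.survival_at(t)[0]) for c in curves.values()]
        risky = [int((ts >= t).sum()) for ts in stratum_times.values()]
        if all(0.0 < s < 1.0 for s in vals) and all(r >= min_at_risk for r in risky):
            grid.append(t)
    grid = np.asarray(grid)
    loglog = {
        lvl: np.log(-np.log(c.survival_at(grid))) for lvl, c in curves.items()
    }
    if len(curves) == 2 and len(grid) > 0:
        gap = loglog[1] - loglog[0]
        # summarize on equal-count time bins: pointwise KM noise in the tails
        # would otherwise dominate the range statistic
        n_bins = min(10, len(gap))
        bins = np.array_split(gap, n_bins)
        means = np.array([b.mean() for b in bins])
        gap_range = float(means.max() - means.min())
        gap_mean = float(gap.mean())
        sign_change = bool(means.min() < 0 < means.max())
    else:
        gap = np.zeros(0)
        gap_range = float("nan")
        gap_mean = float("nan")
        sign_change = False
    return LogLogCheck(
        grid=grid,
        curves=loglog,
        gap=gap,
        gap_range=gap_range,
        gap_mean=gap_mean,
        sign_change=sign_change,
    )


def plot_km(curves: dict[str, KMCurve], path=None, title: str = "Kaplan-Meier"):
    """Step plot of one or more KM curves (saved to ``path`` if given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, c in curves.items():
        ax.step(
            np.concatenate([[0.0], c.times]),
            np.concatenate([[1.0], c.survival]),
            where="post",
            label=str(label),
        )
    ax.set_xlabel("months since diagnosis")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    if len(curves) > 1:
        ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
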