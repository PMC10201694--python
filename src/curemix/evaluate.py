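"""Model evaluation and reporting: Wald coefficient tables (OR/HR with 95%
CIs), the K-index concordance for cure models, and model comparison."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort
from .cure_frailty import FrailtyCureFit, marginal_uncured_survival
from .cure_ph import CureFit
from .km import kaplan_meier


@dataclass(frozen=True)
class WaldRow:
    """One coefficient row: ratio = exp(coef), CI = exp(coef -/+ 1.96 SE)."""

    variable: str
    part: str  # "incidence" (OR) or "latency" (HR)
    coef: float
    se: float | None
    ratio: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None


def wald_row(variable: str, part: str, coef: float, se: float | None) -> WaldRow:
    ratio = float(np.exp(coef))
    if se is None or not np.isfinite(se):
        return WaldRow(variable, part, coef, None, ratio, None, None, None)
    lo = float(np.exp(coef - 1.96 * se))
    hi = float(np.exp(coef + 1.96 * se))
    p = 1.0 if se == 0 and coef == 0 else float(2.0 * norm.sf(abs(coef) / se)) if se > 0 else 0.0
    return WaldRow(variable, part, coef, se, ratio, lo, hi, p)


def wald_table(fit: CureFit) -> pd.DataFrame:
    """Coefficient/SE/ratio/95% CI table for both model parts.

    Incidence rows report odds ratios of being uncured; latency rows report
    hazard ratios among the uncured. For a frailty fit a final additive row
    reports psi with its (bootstrap) SE and CI. Displayed p-values floor at
    0.001. Missing SEs leave the CI columns empty with a note row flag.
    """
    rows = []
    inc_se = fit.incidence.se if fit.incidence.se is not None else [None] * len(fit.incidence.coef)
    for name, c, s in zip(["intercept", *fit.incidence.names], fit.incidence.coef, inc_se):
        rows.append(wald_row(name, "incidence", float(c), None if s is None else float(s)))
    lat_se = fit.latency.se if fit.latency.se is not None else [None] * len(fit.latency.coef)
    for name, c, s in zip(fit.latency.names, fit.latency.coef, lat_se):
        rows.append(wald_row(name, "latency", float(c), None if s is None else float(s)))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if isinstance(fit, FrailtyCureFit):
        ci = fit.psi_ci
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    [
                        {
                            "variable": "frailty_variance",
                            "part": "frailty",
                            "coef": fit.psi,
                            "se": fit.psi_se,
                            "ratio": np.nan,
                            "ci_low": None if ci is None else ci[0],
                            "ci_high": None if ci is None else ci[1],
                            "p_value": None,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return df


def format_wald_table(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: 3 decimals; p-values below 0.001 shown as 0.001."""
    out = df.copy()
    for col in ("coef", "se", "ratio", "ci_low", "ci_high"):
        out[col] = out[col].map(lambda v: None if v is None or pd.isna(v) else round(float(v), 3))
    out["p_value"] = out["p_value"].map(
        lambda v: None if v is None or pd.isna(v) else max(round(float(v), 3), 0.001)
    )
    return out


# -- K-index -----------------------------------------------------------------


def _population_mortality_risk(fit: CureFit, cohort: Cohort, times: np.ndarray) -> np.ndarray:
    """Matrix F[i, j] = 1 - S_pop(times[i] | X_j, Z_j)."""
    Z = cohort.covariate_matrix(fit.incidence.names)
    X = cohort.covariate_matrix(fit.latency.names)
    pi = fit.incidence.uncured_probability(Z)  # (n,)
    H0 = fit.latency.baseline_cum_hazard(times)  # (T,)
    relhaz = np.exp(X @ fit.latency.coef)  # (n,)
    H = H0[:, None] * relhaz[None, :]
    if isinstance(fit, FrailtyCureFit):
        s_u = marginal_uncured_survival(H, fit.psi)
    else:
        s_u = np.exp(-H)
    if fit.latency.zero_tail:
        s_u = np.where(times[:, None] > fit.latency.last_event_time + 1e-12, 0.0, s_u)
    return pi[None, :] * (1.0 - s_u)


def k_index(fit: CureFit, cohort: Cohort, ipcw: bool = False) -> float:
    """Concordance for cure models on population mortality risk.

    Over comparable pairs (i, j) with t_i < t_j and subject i dead, the pair
    is concordant when i's predicted population mortality risk at t_i,
    1 - S_pop(t_i | X_i, Z_i), exceeds j's risk evaluated at the same time;
    ties count 1/2. With ``ipcw=True`` each pair is weighted by the inverse
    squared censoring survival G(t_i)^-2 (Kaplan–Meier of the censoring
    distribution), down-weighting late, heavily censored event times.
    """
    time, event = cohort.time, cohort.event
    deaths = np.flatnonzero(event == 1)
    if len(deaths) == 0:
        raise ValueError("K-index undefined: no events")
    t_i = time[deaths]
    F = _population_mortality_risk(fit, cohort, t_i)  # (D, n)
    if ipcw:
        cens_km = kaplan_meier(time, 1 - event)
        g = np.maximum(cens_km.survival_at(t_i), 1e-4)
        weights = 1.0 / g**2
    else:
        weights = None
    return _concordance_from_risk(F, time, deaths, weights)


def _concordance_from_risk(F: np.ndarray, time: np.ndarray, deaths: np.ndarray, weights=None) -> float:
    """Pairwise concordance given F[i, j] = risk of subject j at death time i."""
    t_i = time[deaths]
    risk_i = F[np.arange(len(deaths)), deaths]
    comparable = time[None, :] > t_i[:, None]  # j still at risk after t_i
    if not comparable.any():
        raise ValueError("K-index undefined: no comparable pairs")
    conc = (risk_i[:, None] > F + 1e-12) & comparable
    ties = (np.abs(risk_i[:, None] - F) <= 1e-12) & comparable
    w = np.ones((len(deaths), 1)) if weights is None else np.asarray(weights)[:, None]
    num = float((w * (conc + 0.5 * ties)).sum())
    den = float((w * comparable).sum())
    return num / den


# -- comparison --------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Per-model K-index / log-likelihood and the K-index-preferred model."""

    models: list[str]
    k_indices: list[float]
    logliks: list[float]
    n_parameters: list[int]
    preferred: str
    tie: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "k_index": self.k_indices,
                "loglik": self.logliks,
                "n_parameters": self.n_parameters,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "models": self.models,
                "k_indices": self.k_indices,
                "logliks": self.logliks,
                "n_parameters": self.n_parameters,
                "preferred": self.preferred,
                "tie": self.tie,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ComparisonReport":
        raw = json.loads(payload)
        return cls(
            models=raw["models"],
            k_indices=raw["k_indices"],
            logliks=raw["logliks"],
            n_parameters=raw["n_parameters"],
            preferred=raw["preferred"],
            tie=raw["tie"],
        )


def compare_models(fits: list[CureFit], cohort: Cohort, labels: list[str] | None = None) -> ComparisonReport:
    """Tabulate K-index and log-likelihood; prefer the larger K-index.

    All fits must have been obtained on the given cohort (checked by
    posterior length). Exact K-index ties are reported as such, with the
    first model named."""
    if len(fits) < 2:
        raise ValueError("compare_models needs at least two fits")
    for f in fits:
        if len(f.posteriors) != cohort.n:
            raise ValueError("fit does not match the cohort (different n)")
    labels = labels if labels is not None else [f.model_name for f in fits]
    ks = [k_index(f, cohort) for f in fits]
    lls = [f.loglik for f in fits]
    best = int(np.argmax(ks))
    tie = bool(np.isclose(max(ks), min(ks)))
    return ComparisonReport(
        models=list(labels),
        k_indices=ks,
        logliks=lls,
        n_parameters=[f.n_parameters for f in fits],
        preferred=labels[best],
        tie=tie,
    )
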