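"""Covariate preprocessing: multiple imputation of missing binary covariates
and collinearity screening via variance inflation factors."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort, CohortError


class ImputationError(ValueError):
    pass


def impute_missing(cohort: Cohort, n_imputations: int = 5, seed: int | None = None) -> list[Cohort]:
    """Multiple regression imputation of missing binary covariates.

    Each covariate with missing cells is modelled by a logistic regression on
    all fully observed covariates plus follow-up time and the event indicator;
    missing cells are filled by Bernoulli draws from the predicted
    probabilities, independently for each of the ``n_imputations`` completed
    cohorts. Observed cells are never altered; time and event are never
    imputed. Deterministic under a fixed ``seed``.
    """
    if n_imputations < 1:
        raise ImputationError("n_imputations must be >= 1")
    df = cohort.data
    names = cohort.covariate_names
    incomplete = [c for c in names if df[c].isna().any()]
    all_missing = [c for c in incomplete if df[c].isna().all()]
    if all_missing:
        raise ImputationError(f"covariates missing for every subject: {all_missing}")
    if not incomplete:
        return [cohort.copy() for _ in range(n_imputations)]

    complete = [c for c in names if c not in incomplete]
    rng = np.random.default_rng(seed)
    # predictors: fully observed covariates + standardized time + event
    t = df["time"].to_numpy(dtype=float)
    t_std = (t - t.mean()) / (t.std() or 1.0)
    base = np.column_stack([df[complete].to_numpy(dtype=float), t_std, df["event"].to_numpy(dtype=float)]) \
        if complete else np.column_stack([t_std, df["event"].to_numpy(dtype=float)])

    probs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in incomplete:
        y = df[c].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        mis = ~obs
        y_obs = y[obs]
        if len(np.unique(y_obs)) < 2:
            # constant among observed: impute with the observed proportion
            p = np.full(mis.sum(), float(y_obs.mean()))
        else:
            # light ridge keeps the fit defined under quasi-separation
            model = LogisticRegression(C=1000.0, max_iter=2000)
            model.fit(base[obs], y_obs)
            p = model.predict_proba(base[mis])[:, 1]
        probs[c] = (mis, p)

    out = []
    for _ in range(n_imputations):
        filled = df.copy()
        for c in incomplete:
            mis, p = probs[c]
            draws = (rng.random(mis.sum()) < p).astype(float)
            col = filled[c].to_numpy(dtype=float)
            col[mis] = draws
            filled[c] = col
        out.append(Cohort(filled, cohort.schema))
    return out


def pool_rubin(estimates: Sequence[np.ndarray], variances: Sequence[np.ndarray]) -> dict:
    """Rubin's rules for pooling estimates across m imputed-data fits.

    Returns pooled estimates, total variance (within + (1+1/m)·between),
    and the pooled standard errors.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.shape[0]
    if m < 2:
        raise ImputationError("pooling requires at least two imputations")
    qbar = q.mean(axis=0)
    within = u.mean(axis=0)
    between = q.var(axis=0, ddof=1)
    total = within + (1 + 1 / m) * between
    return {"estimate": qbar, "variance": total, "se": np.sqrt(total), "m": m}


@dataclass
class VifTable:
    """Variance inflation factors; ``inf`` flags exact collinearity."""

    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def collinear(self) -> list[str]:
        return [k for k, v in self.values.items() if not np.isfinite(v)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"covariate": list(self.values), "vif": list(self.values.values())}
        )


def compute_vif(cohort: Cohort, covariate_names: Sequence[str] | None = None) -> VifTable:
    """VIF_j = 1 / (1 - R²_j) from regressing covariate j on all the others.

    Exact collinearity (R² = 1 to machine precision) is flagged as ``inf``
    rather than raised. Requires complete covariates.
    """
    names = list(covariate_names) if covariate_names is not None else cohort.covariate_names
    X = cohort.data[names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise CohortError("compute_vif requires complete covariates; impute first")
    n = X.shape[0]
    values: dict[str, float] = {}
    for j, name in enumerate(names):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        tss = float(((y - y.mean()) ** 2).sum())
        if tss == 0.0:
            values[name] = float("nan")  # degenerate (constant) covariate
            continue
        r2 = 1.0 - float((resid**2).sum()) / tss
        values[name] = float("inf") if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return VifTable(values)
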