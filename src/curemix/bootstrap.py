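"""Nonparametric bootstrap standard errors for the cure-model fits.

Table-style SEs for both EM fitters come from resampling subjects with
replacement and refitting; the SE is the replicate standard deviation.
Replicates that fail to converge are dropped (and counted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .cure_frailty import FrailtyCureFit, fit_mixture_cure_frailty
from .cure_ph import CureFit, fit_mixture_cure_ph


@dataclass
class BootstrapResult:
    se_incidence: np.ndarray  # [intercept, *incidence covariates]
    se_latency: np.ndarray
    se_psi: float | None
    n_replicates: int
    n_dropped: int

    def psi_ci(self, psi_hat: float) -> tuple[float, float] | None:
        if self.se_psi is None:
            return None
        return (psi_hat - 1.96 * self.se_psi, psi_hat + 1.96 * self.se_psi)


def bootstrap_se(
    cohort: Cohort,
    model: str = "cure_ph",
    B: int = 100,
    seed: int | None = None,
    **fit_kwargs,
) -> BootstrapResult:
    """Bootstrap the chosen fitter over ``B`` subject resamples.

    Deterministic under a fixed ``seed``. ``model`` is ``"cure_ph"`` or
    ``"cure_frailty"``; ``fit_kwargs`` are forwarded to the fitter.
    """
    if B < 2:
        raise ValueError("bootstrap requires B >= 2 replicates")
    fitter = {"cure_ph": fit_mixture_cure_ph, "cure_frailty": fit_mixture_cure_frailty}[model]
    rng = np.random.default_rng(seed)
    inc, lat, psis = [], [], []
    dropped = 0
    n = cohort.n
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        resampled = Cohort(cohort.data.iloc[idx].reset_index(drop=True), cohort.schema)
        if resampled.n_events < 1:
            dropped += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fitter(resampled, **fit_kwargs)
        except Exception:
            dropped += 1
            continue
        if not fit.converged:
            dropped += 1
            continue
        inc.append(fit.incidence.coef)
        lat.append(fit.latency.coef)
        if isinstance(fit, FrailtyCureFit):
            psis.append(fit.psi)
    if len(inc) < 2:
        raise RuntimeError(f"bootstrap failed: only {len(inc)} usable replicates of {B}")
    inc = np.asarray(inc)
    lat = np.asarray(lat)
    return BootstrapResult(
        se_incidence=inc.std(axis=0, ddof=1),
        se_latency=lat.std(axis=0, ddof=1),
        se_psi=float(np.std(psis, ddof=1)) if psis else None,
        n_replicates=len(inc),
        n_dropped=dropped,
    )


def attach_bootstrap_se(fit: CureFit, cohort: Cohort, B: int = 100, seed: int | None = None, **fit_kwargs) -> CureFit:
    """Convenience: run the bootstrap and store the SEs on the fit in place."""
    model = fit.model_name
    res = bootstrap_se(cohort, model=model, B=B, seed=seed, **fit_kwargs)
    fit.incidence.se = res.se_incidence
    fit.latency.se = res.se_latency
    if isinstance(fit, FrailtyCureFit):
        fit.psi_se = res.se_psi
        fit.psi_ci = res.psi_ci(fit.psi)
    return fit
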