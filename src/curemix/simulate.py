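"""Synthetic mixture-cure cohorts with known ground truth.

The generator draws, per subject:

1. independent Bernoulli covariates with configurable marginal prevalences;
2. a latent cure status v ~ Bernoulli(pi(Z)), pi = logistic(theta'Z)
   (v = 1 means *uncured*, i.e. susceptible to death);
3. for uncured subjects a gamma frailty w ~ Gamma(1/psi, psi) (mean 1,
   variance psi; w = 1 when psi = 0) and an event time from the hazard
   w * h0(t) * exp(beta'X), sampled exactly by inverting the conditional
   cumulative hazard; cured subjects never fail (latent time = infinity);
4. a censoring time = min(administrative censoring under uniform staggered
   entry over the accrual window, independent exponential dropout).

Observed time is min(latent event time, censoring time); the default
configuration emulates a 2170-subject HIV registry with ten binary
covariates, a logistic cure-incidence layer, gamma frailty variance 0.380
and ~57.5% censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import reference
from .cohort import Cohort, CovariateSchema


class ConfigError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class WeibullBaseline:
    """Baseline hazard h0(t) = (shape/scale) * (t/scale)^(shape-1), t in months."""

    shape: float
    scale: float

    def cum_hazard(self, t):
        return (np.asarray(t, dtype=float) / self.scale) ** self.shape

    def inverse_cum_hazard(self, h):
        return self.scale * np.asarray(h, dtype=float) ** (1.0 / self.shape)


@dataclass
class GeneratorConfig:
    """Simulation parameters; defaults must be overridden or taken from
    :func:`default_hiv_config`."""

    n: int
    prevalences: dict[str, float]
    theta: dict[str, float]  # incidence coefficients, incl. "intercept"
    beta: dict[str, float]  # latency coefficients
    baseline: WeibullBaseline
    psi: float = 0.0
    accrual_months: float = 252.0  # uniform staggered entry over this window
    horizon_months: float = 252.0  # administrative study end
    dropout_rate: float = 0.0  # per-month exponential dropout hazard
    seed: int | None = None
    schema: CovariateSchema = field(default_factory=CovariateSchema.default_hiv)

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.psi < 0:
            raise ConfigError("frailty variance psi must be >= 0")
        for k, p in self.prevalences.items():
            if not 0 < p < 1:
                raise ConfigError(f"prevalence for {k!r} must lie in (0,1)")
        if self.baseline.shape <= 0 or self.baseline.scale <= 0:
            raise ConfigError("baseline Weibull shape and scale must be positive")
        if not 0 < self.accrual_months <= self.horizon_months:
            raise ConfigError("need 0 < accrual_months <= horizon_months")
        if self.dropout_rate < 0:
            raise ConfigError("dropout_rate must be >= 0")
        if "intercept" not in self.theta:
            raise ConfigError("theta must contain an 'intercept' entry")

    def to_yaml(self, path) -> None:
        raw = {
            "n": self.n,
            "prevalences": self.prevalences,
            "theta": self.theta,
            "beta": self.beta,
            "baseline": {"family": "weibull", "shape": self.baseline.shape, "scale": self.baseline.scale},
            "psi": self.psi,
            "accrual_months": self.accrual_months,
            "horizon_months": self.horizon_months,
            "dropout_rate": self.dropout_rate,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        bl = raw.pop("baseline")
        if bl.get("family", "weibull") != "weibull":
            raise ConfigError(f"unsupported baseline family {bl.get('family')!r}")
        return cls(baseline=WeibullBaseline(bl["shape"], bl["scale"]), **raw)


def default_hiv_config(n: int = reference.COHORT_SIZE, seed: int | None = None) -> GeneratorConfig:
    """Study conditions of the HIV reference cohort.

    Prevalences are the published marginals; theta and beta are the published
    mixture-cure-frailty coefficients; psi = 0.380. The Weibull baseline puts
    the uncured median death time on the month scale of the published KM curve,
    and the censoring mechanism is pre-calibrated (see
    :func:`calibrate_censoring`) so the expected censoring fraction is 57.5%.
    """
    theta = reference.reference_coefficients("cure_frailty", "incidence")
    beta = reference.reference_coefficients("cure_frailty", "latency")
    cfg = GeneratorConfig(
        n=n,
        prevalences=dict(reference.PREVALENCES),
        theta=theta,
        beta=beta,
        baseline=WeibullBaseline(shape=0.9, scale=32.0),
        psi=reference.FRAILTY_VARIANCE[0],
        accrual_months=252.0,
        horizon_months=252.0,
        dropout_rate=0.0,
        seed=seed,
    )
    cfg.validate()
    return cfg


def _linear_predictors(cfg: GeneratorConfig, Z: np.ndarray, names: list[str]):
    theta0 = cfg.theta["intercept"]
    th = np.array([cfg.theta[c] for c in names])
    be = np.array([cfg.beta.get(c, 0.0) for c in names])
    return theta0 + Z @ th, Z @ be


def simulate_cohort(cfg: GeneratorConfig, seed: int | None = None) -> tuple[Cohort, pd.DataFrame]:
    """Draw one cohort; returns (cohort, latent truth table).

    The truth table records, per subject: the latent uncured indicator ``v``,
    the frailty draw ``w``, the latent (possibly infinite) event time, the
    cure probability 1 - pi(Z), and the censoring time actually applied.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    names = list(cfg.prevalences)
    n = cfg.n

    Z = (rng.random((n, len(names))) < np.array([cfg.prevalences[c] for c in names])).astype(float)
    eta_inc, eta_lat = _linear_predictors(cfg, Z, names)
    pi = expit(eta_inc)
    v = (rng.random(n) < pi).astype(int)

    w = np.ones(n)
    if cfg.psi > 0:
        uncured = v == 1
        w[uncured] = rng.gamma(shape=1.0 / cfg.psi, scale=cfg.psi, size=int(uncured.sum()))

    latent = np.full(n, np.inf)
    uncured = v == 1
    e = rng.exponential(size=int(uncured.sum()))
    latent[uncured] = cfg.baseline.inverse_cum_hazard(e / (w[uncured] * np.exp(eta_lat[uncured])))

    entry = rng.uniform(0.0, cfg.accrual_months, size=n)
    admin = cfg.horizon_months - entry
    if cfg.dropout_rate > 0:
        dropout = rng.exponential(1.0 / cfg.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(admin, dropout)

    time = np.minimum(latent, censor)
    event = (latent <= censor).astype(int)

    data = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], "time": time, "event": event})
    for j, c in enumerate(names):
        data[c] = Z[:, j]
    schema = replace(cfg.schema) if set(cfg.schema.covariates) == set(names) else CovariateSchema(names)
    cohort = Cohort(data, schema)
    truth = pd.DataFrame(
        {
            "subject_id": data["subject_id"],
            "v": v,
            "w": w,
            "latent_event_time": latent,
            "cure_probability": 1.0 - pi,
            "censor_time": censor,
        }
    )
    return cohort, truth


def _censoring_fraction(cfg: GeneratorConfig, n_mc: int, seed: int) -> float:
    probe = replace(cfg, n=n_mc, seed=seed)
    cohort, _ = simulate_cohort(probe)
    return 1.0 - cohort.n_events / cohort.n


def calibrate_censoring(
    cfg: GeneratorConfig,
    target_rate: float,
    tolerance: float = 0.01,
    n_mc: int = 20000,
    seed: int = 0,
) -> GeneratorConfig:
    """Tune the censoring mechanism to an expected censoring fraction.

    Only the censoring mechanism moves: the exponential dropout rate is
    raised to add censoring; the administrative horizon is extended (with
    dropout removed) to shed censoring. Cured subjects are always censored,
    so targets at or below the cure fraction are unreachable and raise
    :class:`CalibrationError`. Monte Carlo evaluation with common random
    numbers keeps the search deterministic.
    """
    if not 0 < target_rate < 1:
        raise CalibrationError("target_rate must lie strictly between 0 and 1")
    cfg.validate()
    base = replace(cfg, dropout_rate=0.0)
    f0 = _censoring_fraction(base, n_mc, seed)

    # lower bound: with infinite follow-up only the cured remain censored
    names = list(cfg.prevalences)
    rng = np.random.default_rng(seed)
    Z = (rng.random((n_mc, len(names))) < np.array([cfg.prevalences[c] for c in names])).astype(float)
    cure_frac = float(np.mean(1.0 - expit(_linear_predictors(cfg, Z, names)[0])))

    if target_rate <= cure_frac + 0.5 * tolerance:
        raise CalibrationError(
            f"target censoring {target_rate:.3f} is at or below the cure fraction "
            f"{cure_frac:.3f}; cured subjects are always censored"
        )

    if f0 <= target_rate:
        # add exponential dropout; censoring is increasing in the rate
        lo, hi = 0.0, 1e-4
        while _censoring_fraction(replace(base, dropout_rate=hi), n_mc, seed) < target_rate:
            hi *= 4.0
            if hi > 10.0:
                raise CalibrationError("could not bracket the dropout rate")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            f = _censoring_fraction(replace(base, dropout_rate=mid), n_mc, seed)
            if abs(f - target_rate) < 0.25 * tolerance:
                lo = hi = mid
                break
            if f < target_rate:
                lo = mid
            else:
                hi = mid
        out = replace(cfg, dropout_rate=0.5 * (lo + hi))
    else:
        # too much censoring even without dropout: extend the horizon
        scale_lo, scale_hi = 1.0, 2.0
        def frac_at(s):
            probe = replace(
                base,
                horizon_months=base.horizon_months * s,
                accrual_months=base.accrual_months,
            )
            return _censoring_fraction(probe, n_mc, seed)
        while frac_at(scale_hi) > target_rate:
            scale_hi *= 2.0
            if scale_hi > 1024:
                raise CalibrationError(
                    f"target {target_rate:.3f} unreachable: censoring cannot drop "
                    f"below the cure fraction {cure_frac:.3f}"
                )
        for _ in range(60):
            mid = 0.5 * (scale_lo + scale_hi)
            f = frac_at(mid)
            if abs(f - target_rate) < 0.25 * tolerance:
                scale_lo = scale_hi = mid
                break
            if f > target_rate:
                scale_lo = mid
            else:
                scale_hi = mid
        s = 0.5 * (scale_lo + scale_hi)
        out = replace(cfg, horizon_months=cfg.horizon_months * s, dropout_rate=0.0)

    achieved = _censoring_fraction(replace(out, dropout_rate=out.dropout_rate), n_mc, seed + 1)
    if abs(achieved - target_rate) > tolerance:
        raise CalibrationError(
            f"calibration landed at {achieved:.3f}, outside +/-{tolerance} of {target_rate}"
        )
    return out
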