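# Methods

## Models

**Semiparametric PH mixture cure model.** Each subject carries a latent
indicator v (1 = uncured/susceptible, 0 = cured). The population survival is
S_pop(t|X,Z) = π(Z)·S_u(t|X) + 1 − π(Z) with logistic incidence
π(Z) = expit(θᵀZ) (intercept included) and Cox latency
S_u(t|X) = exp(−H₀(t)·e^{βᵀX}), H₀ a nondecreasing step function with
increments only at observed death times (Breslow). Deaths identify v = 1;
censored subjects are a mixture.

**Gamma-frailty mixture cure model.** Conditional on v = 1 the hazard is
w·h₀(t)·e^{βᵀX} with w ~ Gamma(1/Ψ, Ψ) (mean 1, variance Ψ ≥ 0).
Marginally over w the uncured survival is (1 + Ψ H(t))^{−1/Ψ}, continuous
at Ψ = 0 where it reduces to the non-frailty model. Ψ captures unmeasured
subject-level heterogeneity; a significantly positive Ψ says the measured
covariates do not exhaust the mortality differences among the susceptible.

Both models are intended for cohorts where a Kaplan–Meier plateau and the
Maller–Zhou test support a cure fraction, and where follow-up extends well
past the last observed death.

## Estimation

EM over the latent (v, w):

* **E-step.** E[v_i] = 1 for deaths; for censored subjects
  π_i S_i /(1 − π_i + π_i S_i) with S_i the (frailty-marginal) uncured
  survival at t_i. Gamma conjugacy gives the frailty posterior
  Gamma(1/Ψ + δ_i, Ψ/(1 + Ψ H_i)) — only E[w|·] = (1+Ψδ)/(1+ΨH) and
  E[log w|·] = digamma(1/Ψ+δ) + log(Ψ/(1+ΨH)) are needed.
* **M-step.** θ by a fractional-response logistic GLM of E[v] on Z. (β, H₀)
  by a weighted Breslow partial likelihood in which subject j enters every
  risk set multiplied by E[v_j] (PH cure) or E[v_j]·E[w_j | uncured]
  (frailty); deaths contribute once each. The solver is a dedicated
  Newton–Raphson on the weighted partial likelihood — off-the-shelf Cox
  fitters do not expose risk weights that differ from event weights — and
  is cross-checked against lifelines and statsmodels `PHReg` in the tests.
* **Frailty variance.** Ψ is updated by directly maximizing the observed
  log-likelihood in Ψ with the other parameters held fixed (bounded Brent
  on log Ψ ∈ [log 1e-8, log 50]; an ECME-style conditional maximization).
  The classical EM update — solving the expected-gamma-density score
  log a − digamma(a) = −1 − mean(E[log w] − E[w]) for a = 1/Ψ — is retained
  in the code for reference but is not used: the profile likelihood in Ψ is
  extremely flat, and the classical update crawls along that ridge so
  slowly that fits routinely stalled short of the optimum (including
  free-Ψ fits ending *below* the Ψ=0 fit). The conditional maximization
  preserves the monotone-likelihood guarantee, which is asserted on every
  fit.

**Zero-tail constraint** (default on): S_u(t) ≡ 0 beyond the largest
observed death time. This is required for identifiability of the
nonparametric latency tail — without it, mass for late-censored subjects
can be attributed either to cure or to an unobserved latency tail. A
consequence used by the E-step: subjects censored after the last death are
classified as cured with certainty.

**Convergence** is declared when the relative change of the observed-data
log-likelihood drops below `tol` (default 1e-7, `max_iter` 500). Ties use
the Breslow approximation throughout, consistent with the baseline update.
Initialization: θ from a logistic regression of the event indicator on Z,
β from a plain Cox fit — EM is initialization-sensitive, and this start
point is deliberately deterministic.

**Standard errors** are nonparametric bootstrap over subjects (default
B = 100; replicates that fail to converge are dropped and counted). Wald
tables report exp(coef) and exp(coef ± 1.96·SE); 1.96 rather than a
t quantile — the convention back-computed from the published tables this
package reproduces. A profile-likelihood CI for Ψ (`profile_psi_ci`) and a
boundary-corrected likelihood-ratio test for Ψ = 0 (50:50 mixture of χ²₀
and χ²₁) are available, since the bootstrap interval for a
boundary-constrained parameter can cover negative values.

## Diagnostics

* **Kaplan–Meier** estimation is delegated to lifelines; the curve is
  re-exposed with at-risk/event/censoring counts and a step evaluator. The
  terminal plateau is the span from the last death to the last observed
  time; its level estimates the cure fraction.
* **Maller–Zhou.** The cure fraction estimate is Ŝ_KM(t*) at the largest
  death time t*; H₀ (no cure) is tested one-sided with the Greenwood
  standard error — the literature offers several variants, so the
  construction is documented here as an implementation choice. Follow-up
  sufficiency uses N_n, the number of deaths in (2t* − t_max, t*], with
  approximate p-value (1 − N_n/n)^n.
* **ln(−ln S) parallelism.** Stratified curves are computed on the common
  grid of death times where each stratum's survival lies strictly in (0,1)
  and has ≥ 15 subjects at risk. The range/sign diagnostics are computed on
  10 equal-count time-bin means of the vertical gap: the pointwise KM tail
  noise would otherwise dominate the range statistic (observed range ≈ 1.5
  under exact PH at n = 4000 versus ≈ 0.1 after binning). This is a
  descriptive diagnostic, not a formal test.
* **VIF** is computed as 1/(1 − R²) from least-squares regressions of each
  covariate on the others; exact collinearity is flagged (∞), not raised.
* **Multiple imputation** of missing binary covariates: logistic regression
  of each incomplete covariate on all complete covariates plus
  (standardized) follow-up time and the event indicator, then Bernoulli
  draws per imputation (default m = 5 — the number is a choice, with no
  external default to follow). A light ridge (C = 1000) keeps fits defined
  under quasi-separation. Rubin's rules pooling is provided but optional
  and off by default; time and event are never imputed.
* **K-index.** Concordance adapted to cure models: over pairs with
  t_i < t_j and subject i dead, the proportion where i's predicted
  population mortality risk at t_i, 1 − S_pop(t_i|X_i,Z_i), exceeds j's
  risk at the same time (ties ½; optional IPCW weighting by the inverse
  squared censoring survival). This pair-based definition is this package's
  operational choice. Note its limits: two fitted cure models that share
  the incidence ranking differ only through small latency re-rankings, so
  their K-indices are typically within ~1e-3 of each other.

## Synthetic cohort generator

`simulate_cohort` draws, per subject: independent Bernoulli covariates with
configurable marginal prevalences; v ~ Bernoulli(expit(θᵀZ)); for the
uncured, w ~ Gamma(1/Ψ, Ψ) and an event time by exact inversion of the
conditional cumulative hazard w·e^{βᵀX}·H₀(T) = −log U with a Weibull
baseline H₀(t) = (t/scale)^shape; censoring is the minimum of
administrative censoring under uniform staggered entry over an accrual
window and an independent exponential dropout. Cured subjects' observed
time is their censoring time. Everything is reproducible under a fixed
seed, and a latent-truth table (v, w, latent event time, cure probability,
censor time) is returned alongside the cohort.

`default_hiv_config` encodes the study conditions the package emulates:
n = 2170; the ten published marginal prevalences; θ and β set to the
published frailty-model coefficients; Ψ = 0.380; accrual and horizon of
252 months (a 21-year registry). The Weibull baseline (shape 0.9,
scale 32 months; uncured median ≈ 21 months, consistent with a cohort
diagnosed late and majority-untreated) was chosen so that administrative
censoring alone yields ≈ 57.5% censoring, the published rate — so the
default dropout rate is 0. `calibrate_censoring` re-tunes only the
censoring mechanism (raising dropout, or extending the horizon) to any
reachable target; targets at or below the cure fraction are impossible and
raise.

What the generator does **not** emulate: covariate dependence (only
marginals are published; an independence copula is used), calendar-time
epidemic dynamics, and the real cohort's entry-time distribution. Passing
tests therefore demonstrate correctness of the estimators under the stated
generating process, not agreement with the unavailable patient data — the
published coefficient estimates themselves are not reproducible targets.

## Numerical choices and edge cases

* Partial-likelihood Newton: exp-centering of the linear predictor, step
  clipping at max |Δβ| = 5 with step-halving, convergence on both
  log-likelihood change and gradient norm.
* EM monotonicity is asserted with tolerance 1e-8·(1 + |ll|); fits that
  exhaust `max_iter` are returned flagged, with posteriors refreshed to be
  consistent with the returned parameters.
* π = 0 in the E-step resolves 0/0 to 0 (a subject who cannot be uncured).
* Exact collinearity, all-missing covariates, zero-event cohorts and
  negative times are caught with named errors; the pipeline wraps failures
  with the stage name.
* Ψ is clamped to [1e-8, 50]; a fit collapsing to the lower bound is
  flagged as a boundary solution.

## Known limitations

* **Ψ is weakly identified** in the semiparametric model: with a free
  baseline, Ψ is identified only through covariate-effect attenuation over
  time. At n ≈ 2000 the profile likelihood is nearly flat over Ψ ∈ [0, 0.4]
  (differences under one log-likelihood unit), so Ψ̂ has large sampling
  spread and positive mass exactly at 0; recovery simulations show the
  estimator is consistent (mean Ψ̂ ≈ 0.39 at n = 6000 against a generating
  0.38) but individual fits should report the LR test or profile CI rather
  than lean on the point estimate. Relatedly, when the generating Ψ is 0,
  Ψ̂ lands exactly on the boundary only about as often as boundary
  asymptotics predict (≈ 50–70%), with the remainder small but positive.
* The K-index separates *models* far more weakly than it separates
  *covariate sets*; comparisons between the two cure models on the same
  data are near-ties and should be read as such.
* No time-varying covariates, no competing risks, no non-gamma frailty
  families, no penalized variable selection.

## Test and script problem sizes

The test suite runs its simulation-based checks at n = 700–2170 with
5–24 replicates and bootstrap B = 24–40; the acceptance script uses five
n = 2170 cohorts. These sizes were chosen so the whole suite completes in
a few minutes on one CPU while keeping Monte-Carlo slack well inside each
assertion's tolerance.
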