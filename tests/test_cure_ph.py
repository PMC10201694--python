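import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import curemix as cm
from curemix.cohort import CohortError
from curemix.cure_ph import LatencyModel, _observed_loglik

from conftest import make_cohort


class TestEStep:
    def test_death_is_uncured(self):
        post = cm.e_step_uncured(np.array([0.3]), np.array([0.9]), np.array([1]))
        assert post[0] == 1.0

    def test_arithmetic_identity(self):
        # pi = 0.5, S_u = 0.5 -> 0.25 / 0.75 = 1/3
        post = cm.e_step_uncured(np.array([0.5]), np.array([0.5]), np.array([0]))
        assert post[0] == pytest.approx(1 / 3)

    def test_pi_zero_guard(self):
        post = cm.e_step_uncured(np.array([0.0]), np.array([0.0]), np.array([0]))
        assert post[0] == 0.0

    def test_zero_tail_classifies_late_censored_as_cured(self, ph_fit, small_cohort):
        time, event = small_cohort.time, small_cohort.event
        beyond = (event == 0) & (time > ph_fit.latency.last_event_time)
        assert beyond.any()
        assert np.all(ph_fit.posteriors[beyond] == 0.0)

    def test_posterior_decreasing_in_censoring_time(self):
        """Later censoring means more evidence of cure (zero-tail on)."""
        time = np.arange(1.0, 21.0)
        event = (time <= 8).astype(int)
        cohort = make_cohort(time, event)
        fit = cm.fit_mixture_cure_ph(cohort)
        cens = fit.posteriors[event == 0]
        assert np.all(np.diff(cens) <= 1e-12)


class TestFit:
    def test_monotone_loglik_and_posterior_range(self, ph_fit):
        trace = np.asarray(ph_fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8 * (1 + np.abs(trace[1:])))
        assert np.all((ph_fit.posteriors >= 0) & (ph_fit.posteriors <= 1))
        assert ph_fit.converged

    def test_deaths_have_posterior_one(self, ph_fit, small_cohort):
        assert np.all(ph_fit.posteriors[small_cohort.event == 1] == 1.0)

    def test_baseline_steps_only_at_event_times(self, ph_fit, small_cohort):
        event_times = np.unique(small_cohort.time[small_cohort.event == 1])
        assert np.array_equal(ph_fit.latency.baseline_times, event_times)
        assert np.all(ph_fit.latency.baseline_increments > 0)

    def test_zero_events_rejected(self):
        with pytest.raises(CohortError):
            cm.fit_mixture_cure_ph(make_cohort([1.0, 2.0], [0, 0]))

    def test_missing_covariates_rejected(self, small_cohort):
        df = small_cohort.data.copy()
        df.loc[0, "art"] = np.nan
        with pytest.raises(CohortError, match="impute"):
            cm.fit_mixture_cure_ph(cm.Cohort(df, small_cohort.schema))

    def test_em_attains_brute_force_likelihood(self):
        """Tiny cohort: direct numerical maximization over (b, beta, step
        heights) cannot beat the EM solution by more than 1e-4."""
        rng = np.random.default_rng(5)
        n = 24
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(2.0, n).round(2) + 0.05
        event = (rng.random(n) < 0.55).astype(int)
        event[np.argmax(t)] = 0  # keep a censored tail so the cure part matters
        cohort = make_cohort(t, event, {"x1": x1, "x2": x2})
        fit = cm.fit_mixture_cure_ph(cohort, tol=1e-10, max_iter=3000)

        time, ev = cohort.time, cohort.event
        X = cohort.covariate_matrix()
        Zd = np.column_stack([np.ones(n), X])
        bl_t = fit.latency.baseline_times
        k = len(bl_t)

        def negll(params):
            b = params[:3]
            beta = params[3:5]
            inc = np.exp(np.clip(params[5:], -30, 30))
            lat = LatencyModel(["x1", "x2"], beta, bl_t, inc, zero_tail=True)
            return -_observed_loglik(expit(Zd @ b), ev, time, X @ beta, lat)

        x0 = np.concatenate(
            [fit.incidence.coef, fit.latency.coef, np.log(fit.latency.baseline_increments)]
        )
        best = -negll(x0)
        starts = [x0] + [x0 + rng.normal(scale=0.5, size=len(x0)) for _ in range(4)]
        starts.append(np.concatenate([np.zeros(5), np.full(k, np.log(1.0 / k))]))
        for s in starts:
            r = minimize(negll, s, method="L-BFGS-B", options={"maxiter": 2000})
            best = max(best, -r.fun)
        assert fit.loglik >= best - 1e-4


class TestPredictions:
    def test_population_survival_limits(self, ph_fit):
        z = {c: 0.0 for c in ph_fit.incidence.names}
        assert cm.population_survival(ph_fit, z, 0.0)[0] == pytest.approx(1.0)
        s = cm.population_survival(ph_fit, z, 50.0)[0]
        cure = cm.cure_probability(ph_fit, z)
        assert cure <= s <= 1.0

    def test_cured_subpopulation_flat_survival(self, ph_fit):
        fit = cm.CureFit(
            incidence=cm.IncidenceModel(ph_fit.incidence.names, np.concatenate([[-50.0], np.zeros(len(ph_fit.incidence.names))])),
            latency=ph_fit.latency,
            loglik_trace=[0.0],
            n_iter=1,
            converged=True,
            posteriors=ph_fit.posteriors,
        )
        z = {c: 0.0 for c in fit.incidence.names}
        for t in (0.0, 10.0, 1e4):
            assert cm.population_survival(fit, z, t)[0] == pytest.approx(1.0)

    def test_uncured_subpopulation_equals_latency_survival(self, ph_fit):
        fit = cm.CureFit(
            incidence=cm.IncidenceModel(ph_fit.incidence.names, np.concatenate([[50.0], np.zeros(len(ph_fit.incidence.names))])),
            latency=ph_fit.latency,
            loglik_trace=[0.0],
            n_iter=1,
            converged=True,
            posteriors=ph_fit.posteriors,
        )
        z = {c: 0.0 for c in fit.incidence.names}
        x = np.zeros(len(fit.latency.names))
        s_pop = cm.population_survival(fit, z, 30.0)[0]
        s_u = fit.latency.uncured_survival(x, 30.0)[0]
        assert s_pop == pytest.approx(s_u, abs=1e-12)

    def test_cure_probability_logistic_symmetry(self, ph_fit):
        names = ph_fit.incidence.names
        fit = cm.CureFit(
            incidence=cm.IncidenceModel(names, np.zeros(len(names) + 1)),
            latency=ph_fit.latency,
            loglik_trace=[0.0],
            n_iter=1,
            converged=True,
            posteriors=ph_fit.posteriors,
        )
        assert cm.cure_probability(fit, {c: 0.0 for c in names}) == pytest.approx(0.5)

    def test_cure_probability_at_published_intercept(self, ph_fit):
        """Intercept-only linear predictor 0.544 -> cure probability
        1 - e^0.544/(1+e^0.544) ~ 0.367."""
        names = ph_fit.incidence.names
        coef = np.concatenate([[0.544], np.zeros(len(names))])
        fit = cm.CureFit(
            incidence=cm.IncidenceModel(names, coef),
            latency=ph_fit.latency,
            loglik_trace=[0.0],
            n_iter=1,
            converged=True,
            posteriors=ph_fit.posteriors,
        )
        assert cm.cure_probability(fit, {c: 0.0 for c in names}) == pytest.approx(
            0.367, abs=5e-4
        )

    def test_extreme_linear_predictor_limit(self, ph_fit):
        names = ph_fit.incidence.names
        coef = np.concatenate([[500.0], np.zeros(len(names))])
        fit = cm.CureFit(
            incidence=cm.IncidenceModel(names, coef),
            latency=ph_fit.latency,
            loglik_trace=[0.0],
            n_iter=1,
            converged=True,
            posteriors=ph_fit.posteriors,
        )
        assert cm.cure_probability(fit, {c: 0.0 for c in names}) == pytest.approx(0.0)


class TestBootstrap:
    def test_seed_reproducibility(self, small_cohort):
        a = cm.bootstrap_se(small_cohort, model="cure_ph", B=5, seed=3)
        b = cm.bootstrap_se(small_cohort, model="cure_ph", B=5, seed=3)
        assert np.array_equal(a.se_incidence, b.se_incidence)
        assert np.array_equal(a.se_latency, b.se_latency)

    def test_degenerate_resampling_gives_zero_se(self, small_cohort, monkeypatch):
        class IdentityRng:
            def integers(self, lo, hi, size):
                return np.arange(size) % hi

        import curemix.bootstrap as bs

        monkeypatch.setattr(bs.np.random, "default_rng", lambda seed=None: IdentityRng())
        res = cm.bootstrap_se(small_cohort, model="cure_ph", B=2, seed=0)
        assert np.allclose(res.se_incidence, 0.0)
        assert np.allclose(res.se_latency, 0.0)

    def test_requires_two_replicates(self, small_cohort):
        with pytest.raises(ValueError):
            cm.bootstrap_se(small_cohort, B=1)
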