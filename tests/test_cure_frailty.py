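import numpy as np
import pytest
from scipy import integrate
from scipy.special import digamma

import curemix as cm
from curemix.cure_ph import LatencyModel

from conftest import make_cohort


class TestGammaFrailtyDensity:
    def test_psi_one_is_standard_exponential(self):
        w = np.array([0.2, 1.0, 3.0])
        assert np.allclose(cm.gamma_frailty_density(w, 1.0), np.exp(-w))

    @pytest.mark.parametrize("psi", [0.1, 0.38, 2.0])
    def test_integrates_to_one(self, psi):
        val, _ = integrate.quad(lambda w: cm.gamma_frailty_density(w, psi), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_mean_one_variance_psi(self):
        psi = 0.38
        m, _ = integrate.quad(lambda w: w * cm.gamma_frailty_density(w, psi), 0, np.inf)
        m2, _ = integrate.quad(lambda w: w * w * cm.gamma_frailty_density(w, psi), 0, np.inf)
        assert m == pytest.approx(1.0, abs=1e-9)
        assert m2 - m * m == pytest.approx(psi, abs=1e-8)

    def test_nonpositive_psi_rejected(self):
        with pytest.raises(ValueError):
            cm.gamma_frailty_density(1.0, 0.0)


class TestMarginalSurvival:
    def test_closed_form_point(self):
        assert cm.marginal_uncured_survival(1.0, 1.0) == pytest.approx(0.5)

    def test_psi_to_zero_limit(self):
        H = np.array([0.3, 1.0, 2.5])
        assert np.allclose(
            cm.marginal_uncured_survival(H, 1e-8), np.exp(-H), atol=1e-6
        )

    @pytest.mark.parametrize("H", [0.5, 1.0, 2.0])
    def test_matches_quadrature(self, H):
        psi = 0.38
        val, _ = integrate.quad(
            lambda w: np.exp(-w * H) * cm.gamma_frailty_density(w, psi), 0, np.inf
        )
        assert cm.marginal_uncured_survival(H, psi) == pytest.approx(val, abs=1e-8)


class TestPosteriorMoments:
    def test_no_data_keeps_prior_mean(self):
        ew, _ = cm.frailty_posterior_moments(0.7, 0.0, 0)
        assert ew == pytest.approx(1.0)

    def test_substitution_point(self):
        ew, _ = cm.frailty_posterior_moments(1.0, 1.0, 0)
        assert ew == pytest.approx(0.5)

    def test_matches_quadrature_ratios(self):
        """Posterior mean and mean-log equal ratios of quadrature integrals
        of the likelihood against the gamma prior."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            psi = rng.uniform(0.1, 2.0)
            H = rng.uniform(0.0, 3.0)
            delta = int(rng.random() < 0.5)

            def lik(w):
                return w**delta * np.exp(-w * H) * cm.gamma_frailty_density(w, psi)

            z, _ = integrate.quad(lik, 0, np.inf)
            m, _ = integrate.quad(lambda w: w * lik(w), 0, np.inf)
            lg, _ = integrate.quad(lambda w: np.log(w) * lik(w), 0, np.inf)
            ew, elog = cm.frailty_posterior_moments(psi, H, delta)
            assert ew == pytest.approx(m / z, abs=1e-8)
            assert elog == pytest.approx(lg / z, abs=1e-8)

    def test_degenerate_psi(self):
        ew, elog = cm.frailty_posterior_moments(0.0, 2.0, 1)
        assert ew == 1.0 and elog == 0.0


class TestCumulativeHazard:
    def test_zero_at_origin_and_ph_scaling(self):
        lat = LatencyModel(["x"], np.array([0.7]), np.array([1.0, 2.0]), np.array([0.2, 0.3]))
        assert lat.cum_hazard(np.array([[1.0]]), 0.0)[0] == 0.0
        h0 = lat.cum_hazard(np.array([[0.0]]), 2.0)[0]
        h1 = lat.cum_hazard(np.array([[1.0]]), 2.0)[0]
        assert h0 == pytest.approx(0.5)  # beta=0 path: raw baseline
        assert h1 == pytest.approx(0.5 * np.exp(0.7))


class TestCompleteDataLoglik:
    @staticmethod
    def _params(psi=1.0):
        theta = np.array([50.0, 0.0])  # pi ~ 1
        beta = np.array([0.0])
        baseline = (np.array([0.5]), np.array([1.0]))
        return (theta, beta, baseline, psi)

    def test_cured_subject_contributes_log_one_minus_pi(self):
        cohort = make_cohort([1.0], [0], {"x": [0.0]})
        theta = np.array([0.2, 0.0])
        ll = cm.complete_data_loglik(
            (theta, np.array([0.0]), (np.array([0.5]), np.array([1.0])), 1.0),
            cohort,
            v=[0],
            w=[1.0],
        )
        from scipy.special import expit

        assert ll == pytest.approx(np.log(1 - expit(0.2)))

    def test_uncensored_free_substitution(self):
        """Uncured censored subject, psi=1, H=1, w=1, pi~1: log(e^-1 * e^-1) = -2."""
        cohort = make_cohort([1.0], [0], {"x": [0.0]})
        ll = cm.complete_data_loglik(self._params(), cohort, v=[1], w=[1.0])
        assert ll == pytest.approx(-2.0, abs=1e-9)

    def test_death_with_cured_label_is_minus_inf(self):
        cohort = make_cohort([0.5], [1], {"x": [0.0]})
        with pytest.warns(UserWarning, match="v=0"):
            ll = cm.complete_data_loglik(self._params(), cohort, v=[0], w=[1.0])
        assert ll == -np.inf

    def test_matches_independent_term_by_term_evaluation(self):
        """Scalar re-implementation of L_{i,c} on random subjects to 1e-12."""
        rng = np.random.default_rng(7)
        n = 20
        x = (rng.random(n) < 0.5).astype(float)
        bl_t = np.sort(rng.uniform(0.1, 5.0, 4))
        bl_inc = rng.uniform(0.05, 0.4, 4)
        ev = (rng.random(n) < 0.5).astype(int)
        # deaths sit on the baseline grid (the step hazard is zero elsewhere)
        t = np.where(ev == 1, rng.choice(bl_t, n), rng.exponential(2.0, n) + 0.1)
        cohort = make_cohort(t, ev, {"x": x})
        theta = np.array([0.3, -0.5])
        beta = np.array([0.6])
        psi = 0.38
        v = np.where(ev == 1, 1, (rng.random(n) < 0.5).astype(int))
        w = rng.gamma(1 / psi, psi, n)

        ll = cm.complete_data_loglik((theta, beta, (bl_t, bl_inc), psi), cohort, v, w)

        from math import exp, lgamma, log

        expected = 0.0
        for i in range(n):
            pi = 1 / (1 + exp(-(0.3 - 0.5 * x[i])))
            if v[i] == 0:
                expected += log(1 - pi)
                continue
            H0 = sum(inc for bt, inc in zip(bl_t, bl_inc) if bt <= t[i])
            h0 = next((inc for bt, inc in zip(bl_t, bl_inc) if bt == t[i]), 0.0)
            Hi = H0 * exp(0.6 * x[i])
            a = 1 / psi
            gdens = (a - 1) * log(w[i]) - w[i] / psi - lgamma(a) - a * log(psi)
            term = log(pi) + gdens - w[i] * Hi
            if ev[i] == 1:
                term += log(w[i] * h0) + 0.6 * x[i]
            expected += term
        assert ll == pytest.approx(expected, abs=1e-12)


class TestFrailtyFit:
    def test_monotone_loglik(self, frailty_fit):
        trace = np.asarray(frailty_fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8 * (1 + np.abs(trace[1:])))
        assert frailty_fit.psi >= 0

    def test_nested_likelihood_dominates_null(self, small_cohort, frailty_fit):
        """Free-psi likelihood dominates the psi=0 fit, up to the EM stopping
        tolerance (tol * (1 + |ll|)) that both fits are allowed to leave."""
        null = cm.fit_mixture_cure_frailty(small_cohort, fix_psi=1e-8, max_iter=2500)
        slack = 2 * 1e-7 * (1 + abs(null.loglik))
        assert frailty_fit.loglik >= null.loglik - slack

    def test_null_frailty_data_shrinks_psi(self):
        """psi=0 generator: the frailty variance estimate collapses."""
        cfg = cm.default_hiv_config(n=1200, seed=31)
        cfg.psi = 0.0
        cohort, _ = cm.simulate_cohort(cfg)
        fit = cm.fit_mixture_cure_frailty(cohort)
        assert fit.psi < 0.15

    def test_boundary_flagged(self):
        cfg = cm.default_hiv_config(n=400, seed=13)
        cfg.psi = 0.0
        cohort, _ = cm.simulate_cohort(cfg)
        fit = cm.fit_mixture_cure_frailty(cohort, fix_psi=None, psi_init=1e-8)
        if fit.psi <= 1e-7:
            assert any("boundary" in f for f in fit.flags)

    def test_lr_test_boundary_mixture(self, small_cohort, frailty_fit):
        null = cm.fit_mixture_cure_frailty(small_cohort, fix_psi=1e-8)
        res = cm.frailty_lr_test(frailty_fit, null)
        assert res["statistic"] >= 0
        assert 0 <= res["p_value"] <= 1

    def test_population_survival_monotone_and_bounded(self, frailty_fit):
        z = {c: 0.0 for c in frailty_fit.incidence.names}
        ts = np.linspace(0, 300, 40)
        s = cm.population_survival_frailty(frailty_fit, z, ts)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all(s >= cm.cure_probability(frailty_fit, z) - 1e-12)


def test_posterior_moment_weights_match_digamma_formula(frailty_fit, small_cohort):
    """Stored posterior frailty moments follow the conjugate formulas."""
    lat = frailty_fit.latency
    X = small_cohort.covariate_matrix(lat.names)
    Hi = lat.baseline_cum_hazard(small_cohort.time) * np.exp(X @ lat.coef)
    psi = frailty_fit.psi
    ew = (1 + psi * small_cohort.event) / (1 + psi * Hi)
    elog = digamma(1 / psi + small_cohort.event) + np.log(psi / (1 + psi * Hi))
    assert np.allclose(frailty_fit.posterior_frailty, ew)
    assert np.allclose(frailty_fit.posterior_log_frailty, elog)
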