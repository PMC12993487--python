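"""Tweedie density, links, IRLS and power/dispersion estimation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import poisson

from glmasca.tweedie import (
    TweedieParams,
    constant_weight_link,
    estimate_power_dispersion,
    get_link,
    irls_fit,
    irls_fit_multi,
    tweedie_log_density,
    tweedie_rvs,
    variance_function,
)


def brute_force_log_a(y, phi, rho, k_max=2000):
    """Independent series evaluation with wide fixed bounds."""
    alpha = (2 - rho) / (rho - 1)
    k = np.arange(1, k_max + 1)
    logw = k * (
        alpha * np.log(y) - alpha * np.log(rho - 1)
        - (1 + alpha) * np.log(phi) - np.log(2 - rho)
    ) - gammaln(k + 1) - gammaln(k * alpha)
    m = logw.max()
    return m + np.log(np.exp(logw - m).sum()) - np.log(y)


class TestDensity:
    def test_zero_mass_closed_form(self):
        # -mu^(2-rho)/(phi*(2-rho)) = -1/(1*0.5) = -2
        assert tweedie_log_density(0.0, 1.0, 1.0, 1.5) == pytest.approx(-2.0)

    @pytest.mark.parametrize("y,mu,phi,rho", [
        (1.3, 2.0, 0.5, 1.5),
        (0.2, 1.0, 1.0, 1.2),
        (7.0, 3.0, 2.0, 1.8),
    ])
    def test_series_matches_brute_force(self, y, mu, phi, rho):
        kernel = (y * mu ** (1 - rho) / (1 - rho) - mu ** (2 - rho) / (2 - rho)) / phi
        expected = kernel + brute_force_log_a(y, phi, rho)
        assert tweedie_log_density(y, mu, phi, rho) == pytest.approx(expected, abs=1e-8)

    def test_poisson_limit_interval_mass(self):
        # as rho -> 1 the density concentrates on the integers; the mass in a
        # unit window around y=2 recovers the Poisson pmf
        mass = quad(
            lambda t: np.exp(tweedie_log_density(t, 2.0, 1.0, 1.001)),
            1.5, 2.5, limit=200,
        )[0]
        assert mass == pytest.approx(poisson.pmf(2, 2.0), abs=1e-2)

    @pytest.mark.parametrize("mu,phi,rho", [
        (1.0, 1.0, 1.5), (2.0, 0.5, 1.3), (0.5, 2.0, 1.7), (3.0, 1.0, 1.9),
    ])
    def test_total_mass_is_one(self, mu, phi, rho):
        p0 = np.exp(tweedie_log_density(0.0, mu, phi, rho))
        upper = mu + 60 * np.sqrt(phi * mu**rho)
        integral = quad(
            lambda t: np.exp(tweedie_log_density(t, mu, phi, rho)),
            1e-12, upper, limit=400,
        )[0]
        assert p0 + integral == pytest.approx(1.0, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tweedie_log_density(1.0, 1.0, 1.0, 2.5)
        with pytest.raises(ValueError):
            tweedie_log_density(-0.5, 1.0, 1.0, 1.5)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            TweedieParams(mu=-1.0, phi=1.0, rho=1.5)
        with pytest.raises(ValueError):
            TweedieParams(mu=1.0, phi=1.0, rho=1.0001 + 1)  # rho=2.0001 unsupported


class TestVarianceFunction:
    def test_closed_forms(self):
        assert variance_function(1.0, 1.7) == pytest.approx(1.0)
        assert variance_function(2.0, 1.5) == pytest.approx(2**1.5)
        assert variance_function(7.0, 0.0) == pytest.approx(1.0)

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            variance_function(0.0, 1.5)


class TestLinks:
    def test_constant_weight_special_cases(self):
        ident = constant_weight_link(0.0, 1.0)
        assert np.allclose(ident.g(np.array([0.3, 2.0])), [0.3, 2.0])
        gamma_log = constant_weight_link(2.0, 1.0)
        mu = np.array([0.5, 1.0, 4.0])
        w = gamma_log.dmu_deta(mu) ** 2 / mu**2
        assert np.allclose(w, 1.0)

    @pytest.mark.parametrize("rho,w", [(1.5, 1.0), (1.5, 3.0), (1.2, 0.5), (3.0, 2.0)])
    def test_induced_weights_are_constant(self, rho, w):
        link = constant_weight_link(rho, w)
        for mu in (0.5, 1.0, 4.0):
            induced = link.dmu_deta(mu) ** 2 / variance_function(mu, rho)
            assert induced == pytest.approx(w, abs=1e-12)
            # round trip
            assert link.g_inv(link.g(mu)) == pytest.approx(mu, rel=1e-10)

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            constant_weight_link(1.5, 0.0)

    def test_log_link_weights_formula(self, rng):
        # for the log link and Tweedie variance, w = mu^(2-rho)
        link = get_link("log")
        mu = rng.uniform(0.2, 30, size=20)
        for rho in (1.1, 1.5, 1.9):
            w = link.dmu_deta(mu) ** 2 / variance_function(mu, rho)
            assert np.allclose(w, mu ** (2 - rho), rtol=1e-12)


class TestIRLS:
    def test_saturated_intercept(self):
        fit = irls_fit(np.array([3.0, 3, 3, 3]), np.ones((4, 1)), rho=1.5)
        assert fit.beta[0] == pytest.approx(np.log(3.0))
        assert np.allclose(fit.mu, 3.0)
        assert np.allclose(fit.working_residuals, 0.0, atol=1e-12)
        assert fit.converged

    def test_gaussian_identity_equals_ols(self, rng):
        X = np.column_stack([np.ones(12), rng.normal(size=12), rng.normal(size=12)])
        y = np.abs(rng.normal(5, 2, size=12))
        fit = irls_fit(y, X, rho=0.0, link="identity")
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, beta_ols, atol=1e-10)
        # unit weights: working response equals the data
        assert np.allclose(fit.working_response, y)

    def test_matches_brute_force_likelihood(self, rng):
        X = np.column_stack([np.ones(8), np.repeat([1.0, -1.0], 4)])
        mu = np.exp(X @ np.array([1.2, 0.6]))
        y = tweedie_rvs(mu, 0.5, 1.5, size=(8,), rng=rng)
        y[y == 0] = 0.5  # keep the oracle's optimum interior
        fit = irls_fit(y, X, rho=1.5)

        def nll(beta):
            m = np.exp(X @ beta)
            return -np.sum(tweedie_log_density(y, m, 0.5, 1.5))

        opt = minimize(nll, np.array([1.0, 0.0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert np.allclose(fit.beta, opt.x, atol=1e-4)

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        mu = np.exp(X @ np.array([2.0, 0.5]))
        y = tweedie_rvs(mu, 0.8, 1.4, size=(20,), rng=rng)
        fit = irls_fit(y, X, rho=1.4)
        ref = sm.GLM(
            y, X, family=sm.families.Tweedie(var_power=1.4, link=sm.families.links.Log())
        ).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-6)

    def test_working_identity_and_weights(self, rng):
        X = np.column_stack([np.ones(10), np.repeat([1.0, -1.0], 5)])
        Y = np.abs(rng.normal(10, 3, size=(10, 4)))
        res = irls_fit_multi(Y, X, 1.5)
        # z = eta + r^w elementwise; w = mu^(2-rho) for the log link
        assert np.allclose(
            res["working_response"], res["eta"] + res["working_residuals"]
        )
        assert np.allclose(res["weights"], res["mu"] ** 0.5, rtol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(np.linalg.LinAlgError, match="columns"):
            irls_fit(np.arange(1.0, 7.0), X, rho=1.5)

    def test_all_zero_response_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            irls_fit(np.zeros(4), np.ones((4, 1)), rho=1.5)

    def test_deviance_nonincreasing_over_iterations(self, rng):
        # once inside the model space, further IRLS iterations (with
        # step-halving) never increase the deviance
        X = np.column_stack([np.ones(16), rng.normal(size=16)])
        y = tweedie_rvs(np.full(16, 5.0), 1.0, 1.6, size=(16,), rng=rng)
        devs = [
            irls_fit(y, X, rho=1.6, max_iter=k).deviance for k in range(1, 8)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(devs, devs[1:]))


class TestPowerDispersion:
    def test_recovers_rho_from_simulation(self, rng):
        y = tweedie_rvs(np.full(2000, 5.0), 1.0, 1.5, size=(2000,), rng=rng)
        rho_hat, phi_hat = estimate_power_dispersion(y, np.ones((2000, 1)))
        assert abs(rho_hat - 1.5) <= 0.1
        assert 0.5 < phi_hat < 2.0

    def test_near_poisson_hits_lower_edge(self, rng):
        y = rng.poisson(50.0, size=1500).astype(float)
        rho_hat, _ = estimate_power_dispersion(y, np.ones((1500, 1)))
        assert rho_hat <= 1.15  # at or adjacent to the grid's lower edge

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            estimate_power_dispersion(np.full(10, 3.0), np.ones((10, 1)))
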