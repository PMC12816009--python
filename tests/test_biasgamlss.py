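"""Inflated-Beta density, distributional fits, GAIC and stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from sleepeval import biasgamlss as bg
from sleepeval.reference_tables import MF1_AUDIT, MF1_E_GENERATING_MODEL
from sleepeval.synthgen import simulate_performance_table


class TestInflatedBetaLogpdf:
    def test_boundary_mass_follows_inflation_intercepts(self):
        nu = tau = np.exp(-22.54)
        lp = bg.inflated_beta_logpdf(0.0, 0.5, 0.3, nu, tau)
        assert lp == pytest.approx(np.log(nu / (1 + nu + tau)), abs=1e-12)
        assert np.exp(lp) < 1e-9

    def test_reduces_to_plain_beta_without_inflation(self):
        mu, sigma = 0.7, 0.4
        c = (1 - sigma**2) / sigma**2
        got = bg.inflated_beta_logpdf(0.3, mu, sigma, 0.0, 0.0)
        assert got == pytest.approx(
            stats.beta.logpdf(0.3, mu * c, (1 - mu) * c), abs=1e-12
        )

    def test_normalizes_to_one_by_quadrature(self, rng):
        for _ in range(15):
            mu = rng.uniform(0.2, 0.8)
            sigma = rng.uniform(0.2, 0.6)
            nu, tau = rng.exponential(0.1, size=2)
            cont, _ = integrate.quad(
                lambda y: np.exp(bg.inflated_beta_logpdf(y, mu, sigma, nu, tau)),
                0.0, 1.0, limit=200,
            )
            denom = 1 + nu + tau
            total = cont + nu / denom + tau / denom
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_out_of_range_arguments_rejected(self):
        with pytest.raises(ValueError):
            bg.inflated_beta_logpdf(1.2, 0.5, 0.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            bg.inflated_beta_logpdf(0.5, 1.0, 0.5, 0.0, 0.0)


class TestCovariateEncoding:
    def test_canonical_coding(self):
        raw = pd.DataFrame(
            {"age": [50, 60], "gender": ["F", "M"], "ahi": [0, 25], "plmi": [10, 0]}
        )
        cov = bg.encode_covariates(raw)
        assert list(cov.loc[0]) == [0.0, 0.0, 0.0, 1.0]
        assert list(cov.loc[1]) == [10.0, 1.0, 2.5, 0.0]

    def test_negative_event_index_rejected(self):
        raw = pd.DataFrame(
            {"age": [50], "gender": ["F"], "ahi": [-1], "plmi": [0]}
        )
        with pytest.raises(ValueError):
            bg.encode_covariates(raw)


def _cov(n, seed=0):
    table = simulate_performance_table(
        {"mu": {"intercept": 0.0}, "sigma": {"intercept": 0.0}}, n, seed
    )
    return bg.encode_covariates(table)


class TestFitting:
    def test_intercept_only_normal_matches_closed_form(self, rng):
        y = rng.normal(3.0, 2.0, size=400)
        fit = bg.fit_distributional_regression(
            y, _cov(400), bg.DistributionalModelSpec("normal")
        )
        assert fit.coef_mu["intercept"] == pytest.approx(y.mean(), abs=1e-6)
        assert np.exp(fit.coef_sigma["intercept"]) == pytest.approx(
            y.std(ddof=0), abs=1e-6
        )

    def test_recovers_published_generating_coefficients(self):
        table = simulate_performance_table(MF1_E_GENERATING_MODEL, n=2000, seed=7)
        cov = bg.encode_covariates(table)
        spec = bg.DistributionalModelSpec(
            "inflated-beta", mu_terms=("gender", "ahi10")
        )
        fit = bg.fit_distributional_regression(table["outcome"].to_numpy(), cov, spec)
        for name, true_val in MF1_E_GENERATING_MODEL["mu"].items():
            assert abs(fit.coef_mu[name] - true_val) <= 3 * fit.se_mu[name]
        true_sig = MF1_E_GENERATING_MODEL["sigma"]["intercept"]
        assert abs(fit.coef_sigma["intercept"] - true_sig) <= (
            3 * fit.se_sigma["intercept"]
        )
        assert not fit.nu_estimable and not fit.tau_estimable

    def test_backfitting_loglik_is_monotone(self):
        table = simulate_performance_table(MF1_E_GENERATING_MODEL, n=500, seed=3)
        cov = bg.encode_covariates(table)
        spec = bg.DistributionalModelSpec(
            "inflated-beta", mu_terms=("gender",), sigma_terms=("ahi10",)
        )
        fit = bg.fit_distributional_regression(table["outcome"].to_numpy(), cov, spec)
        assert np.all(np.diff(fit.loglik_path) >= -1e-10)
        assert fit.converged

    def test_boundary_outcomes_make_inflation_estimable(self, rng):
        gen = {
            "mu": {"intercept": 1.0},
            "sigma": {"intercept": -1.0},
            "log_nu": -3.0,
            "log_tau": -4.0,
        }
        table = simulate_performance_table(gen, n=3000, seed=4)
        fit = bg.fit_distributional_regression(
            table["outcome"].to_numpy(),
            bg.encode_covariates(table),
            bg.DistributionalModelSpec("inflated-beta"),
        )
        assert fit.nu_estimable and fit.tau_estimable
        assert fit.log_nu == pytest.approx(-3.0, abs=0.35)
        assert fit.log_tau == pytest.approx(-4.0, abs=0.5)

    def test_spline_recovers_nonlinear_age_effect(self):
        cov = _cov(500, seed=9)
        eta = 1.0 - 0.0005 * cov["age_c"].to_numpy() ** 2
        mu = special.expit(eta)
        s = special.expit(-1.4)
        c = (1 - s**2) / s**2
        rng = np.random.default_rng(5)
        y = stats.beta.rvs(mu * c, (1 - mu) * c, random_state=rng)
        fit = bg.fit_distributional_regression(
            y, cov,
            bg.DistributionalModelSpec("inflated-beta", mu_terms=("spline(age_c)",)),
        )
        for age_c in (-30.0, 0.0, 30.0):
            prof = bg.expected_profile(fit, {"age_c": age_c})
            truth = float(special.expit(1.0 - 0.0005 * age_c**2))
            assert prof["mu"] == pytest.approx(truth, abs=0.05)


class TestGaic:
    def test_k_two_is_aic_and_k_logn_is_bic(self, rng):
        y = rng.normal(size=200)
        fit = bg.fit_distributional_regression(
            y, _cov(200), bg.DistributionalModelSpec("normal")
        )
        assert bg.gaic(fit, 2.0) == pytest.approx(-2 * fit.loglik + 2 * fit.edf)
        k = np.log(200)
        assert bg.gaic(fit, k) == pytest.approx(-2 * fit.loglik + k * fit.edf)

    def test_noise_covariate_usually_increases_gaic(self):
        increases = 0
        reps = 40
        for i in range(reps):
            table = simulate_performance_table(
                {"mu": {"intercept": 0.0}, "sigma": {"intercept": 0.0}},
                n=150, seed=500 + i, family="normal",
            )
            cov = bg.encode_covariates(table)
            y = table["outcome"].to_numpy()
            base = bg.fit_distributional_regression(
                y, cov, bg.DistributionalModelSpec("normal")
            )
            noisy = bg.fit_distributional_regression(
                y, cov, bg.DistributionalModelSpec("normal", mu_terms=("plmi10",))
            )
            increases += bg.gaic(noisy, 2.0) > bg.gaic(base, 2.0)
        assert increases / reps >= 0.7


class TestForwardStepwise:
    def test_null_outcome_keeps_intercept_only_under_bic_penalty(self):
        kept = 0
        reps = 20
        for i in range(reps):
            table = simulate_performance_table(
                {"mu": {"intercept": 0.0}, "sigma": {"intercept": 0.0}},
                n=150, seed=100 + i, family="normal",
            )
            fit = bg.forward_stepwise(
                table["outcome"].to_numpy(),
                bg.encode_covariates(table),
                family="normal",
                gaic_k=float(np.log(150)),
                lambda_grid=(1.0, 100.0),
            )
            kept += fit.spec.mu_terms == () and fit.spec.sigma_terms == ()
        assert kept / reps >= 0.7

    def test_gender_effect_lands_on_location_not_scale(self):
        correct = 0
        reps = 20
        for i in range(reps):
            table = simulate_performance_table(
                {"mu": {"intercept": 0.0, "gender": 1.0}, "sigma": {"intercept": 0.0}},
                n=150, seed=900 + i, family="normal",
            )
            fit = bg.forward_stepwise(
                table["outcome"].to_numpy(),
                bg.encode_covariates(table),
                family="normal",
                gaic_k=float(np.log(150)),
                lambda_grid=(1.0, 100.0),
            )
            correct += ("gender" in fit.spec.mu_terms) and (
                "gender" not in fit.spec.sigma_terms
            )
        assert correct / reps >= 0.9

    def test_selection_path_is_deterministic(self):
        table = simulate_performance_table(
            {"mu": {"intercept": 1.0, "gender": -0.4}, "sigma": {"intercept": -1.4}},
            n=300, seed=11,
        )
        cov = bg.encode_covariates(table)
        y = table["outcome"].to_numpy()
        kwargs = dict(family="inflated-beta", gaic_k=2.0, lambda_grid=(1.0, 100.0))
        a = bg.forward_stepwise(y, cov, **kwargs)
        b = bg.forward_stepwise(y, cov, **kwargs)
        assert a.selection_path == b.selection_path
        assert a.gaic == b.gaic


class TestExpectedProfile:
    def test_published_mf1_intercept_maps_to_baseline_location(self):
        prof = bg.baseline_profile(
            "inflated-beta",
            MF1_AUDIT["E"]["mu"],
            MF1_AUDIT["E"]["sigma"],
            MF1_AUDIT["E"]["log_nu"],
            MF1_AUDIT["E"]["log_tau"],
        )
        assert prof["mu"] == pytest.approx(special.expit(1.12), abs=1e-12)
        assert prof["mu"] == pytest.approx(0.754, abs=5e-4)
        assert prof["p0"] < 1e-9 and prof["p1"] < 1e-9

    def test_normal_baseline_is_the_intercept_itself(self):
        prof = bg.baseline_profile("normal", -9.05, 2.86)
        assert prof["mu"] == -9.05

    def test_reference_profile_depends_only_on_intercepts(self):
        table = simulate_performance_table(MF1_E_GENERATING_MODEL, n=800, seed=2)
        cov = bg.encode_covariates(table)
        fit = bg.fit_distributional_regression(
            table["outcome"].to_numpy(), cov,
            bg.DistributionalModelSpec("inflated-beta", mu_terms=("gender", "ahi10")),
        )
        prof = bg.expected_profile(fit, {"age_c": 0, "gender": 0, "ahi10": 0})
        assert prof["mu"] == pytest.approx(
            float(special.expit(fit.coef_mu["intercept"])), abs=1e-12
        )

    def test_quantiles_invert_the_mixture_cdf(self):
        table = simulate_performance_table(MF1_E_GENERATING_MODEL, n=500, seed=6)
        fit = bg.fit_distributional_regression(
            table["outcome"].to_numpy(),
            bg.encode_covariates(table),
            bg.DistributionalModelSpec("inflated-beta"),
        )
        prof = bg.expected_profile(fit, {})
        mu, sigma = prof["mu"], prof["sigma"]
        c = (1 - sigma**2) / sigma**2
        for q, x in prof["quantiles"].items():
            assert stats.beta.cdf(x, mu * c, (1 - mu) * c) == pytest.approx(q, abs=1e-9)
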