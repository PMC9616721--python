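"""Gamma-Poisson vs equal-Poisson field-formation models."""

import numpy as np
import pytest
from scipy import integrate, stats

from placepop.field_models import (
    DensityRegression,
    adjusted_area,
    fit_models,
    fit_proportion_regression,
    gamma_poisson_pmf,
    predict_recruitment,
)


def quadrature_pmf(x, alpha, theta, area):
    """Oracle: numerically integrate Pois(x | tau) Gamma(tau; alpha, theta A)."""
    scale = theta * area

    def integrand(tau):
        return stats.poisson.pmf(x, tau) * stats.gamma.pdf(tau, a=alpha, scale=scale)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


class TestPmf:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 5.0])
    @pytest.mark.parametrize("theta_a", [0.5, 2.0])
    def test_matches_quadrature_of_poisson_gamma_mixture(self, alpha, theta_a):
        area = 2.0
        theta = theta_a / area
        for x in (0, 1, 3, 10, 25):
            assert gamma_poisson_pmf(x, alpha, theta, area) == pytest.approx(
                quadrature_pmf(x, alpha, theta, area), abs=1e-8
            )

    def test_normalises_to_one(self):
        xs = np.arange(0, 1000)
        total = gamma_poisson_pmf(xs, 1.2, 0.4, 5.0).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_poisson_limit_at_large_alpha(self):
        # alpha -> inf with alpha * theta * A = 2 approaches Pois(2)
        area, mean = 4.0, 2.0
        alpha = 5e4
        theta = mean / (alpha * area)
        xs = np.arange(0, 15)
        np.testing.assert_allclose(
            gamma_poisson_pmf(xs, alpha, theta, area),
            stats.poisson.pmf(xs, mean),
            atol=2e-5,
        )

    def test_matches_scipy_negative_binomial(self):
        alpha, theta, area = 1.3, 0.35, 6.0
        p = 1.0 / (1.0 + theta * area)
        xs = np.arange(0, 40)
        np.testing.assert_allclose(
            gamma_poisson_pmf(xs, alpha, theta, area),
            stats.nbinom.pmf(xs, alpha, p),
            rtol=1e-12,
        )

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError):
            gamma_poisson_pmf(1.5, 1.0, 1.0, 1.0)


class TestFitModels:
    def test_equal_poisson_mle_is_mean_over_area(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(2.0, size=600)
        area = 4.0
        eq, _, _ = fit_models(x, area)
        assert eq.tau == pytest.approx(x.mean() / area, rel=1e-9)

    def test_recovers_equal_poisson_data(self):
        rng = np.random.default_rng(2)
        area = 2.0
        prefer_eq = 0
        taus = []
        for _ in range(20):
            x = rng.poisson(2.0, size=600)
            eq, gp, preferred = fit_models(x, area)
            taus.append(eq.tau)
            prefer_eq += preferred == "equal_poisson"
        assert abs(np.median(taus) - 1.0) < 0.1
        assert prefer_eq > 10

    def test_recovers_gamma_poisson_parameters(self):
        rng = np.random.default_rng(3)
        area, alpha, theta = 2.0, 1.0, 1.0  # theta * A = 2
        rec_a, rec_t, prefer_gp = [], [], 0
        for _ in range(20):
            taus = rng.gamma(alpha, theta * area, size=627)
            x = rng.poisson(taus)
            eq, gp, preferred = fit_models(x, area)
            rec_a.append(gp.alpha)
            rec_t.append(gp.theta)
            prefer_gp += preferred == "gamma_poisson"
        assert abs(np.median(rec_a) - alpha) / alpha < 0.25
        assert abs(np.median(rec_t) - theta) / theta < 0.25
        assert prefer_gp >= 19

    def test_gamma_loglik_at_least_equal_poisson(self):
        rng = np.random.default_rng(4)
        x = rng.poisson(rng.gamma(1.5, 1.0, size=400))
        eq, gp, _ = fit_models(x, 3.0)
        assert gp.log_likelihood >= eq.log_likelihood - 1e-6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_models(np.zeros(100, dtype=int), 2.0)
        with pytest.raises(ValueError):
            fit_models(np.array([1, 2, 3]), 2.0)


class TestAdjustedArea:
    def test_zero_intercept_is_identity(self):
        reg = DensityRegression(0.05, 0.0)
        assert adjusted_area(3.0, reg) == pytest.approx(3.0)

    def test_offset_is_intercept_over_slope(self):
        # A' = A rho / b with rho = (bA + c)/A reduces to A + c/b
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.uniform(0.5, 20)
            b = rng.uniform(0.01, 1.0)
            c = rng.uniform(0.0, 0.5)
            reg = DensityRegression(b, c)
            assert adjusted_area(a, reg) - a == pytest.approx(c / b, rel=1e-12)

    def test_study_regression_constants(self):
        # printed regression slope 0.038 and intercept 0.093
        reg = DensityRegression(0.038, 0.093)
        assert adjusted_area(5.0, reg) - 5.0 == pytest.approx(0.093 / 0.038, rel=1e-12)
        assert 0.093 / 0.038 == pytest.approx(2.447, abs=5e-4)
        assert adjusted_area(8.75, reg) == pytest.approx(11.197, abs=5e-3)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            adjusted_area(2.0, DensityRegression(0.0, 0.1))


class TestRecruitment:
    def test_single_environment_proportion_is_one(self):
        from placepop.field_models import GammaPoissonFit

        fit = GammaPoissonFit(1.0, 0.3, 0.0, 0.0, 100)
        out = predict_recruitment(fit, {"A": 1.09}, n_cells=20000, seed=0)
        assert out["A"] == pytest.approx(1.0)

    def test_proportions_monotone_in_area(self):
        from placepop.field_models import GammaPoissonFit

        fit = GammaPoissonFit(1.0, 0.3, 0.0, 0.0, 100)
        areas = {"A": 1.09, "B": 2.19, "C": 4.38, "D": 8.75}
        out = predict_recruitment(fit, areas, n_cells=50000, seed=1)
        vals = [out[e] for e in sorted(areas, key=areas.get)]
        assert vals == sorted(vals)

    def test_large_area_saturates(self):
        from placepop.field_models import GammaPoissonFit

        fit = GammaPoissonFit(1.0, 0.3, 0.0, 0.0, 100)
        out = predict_recruitment(fit, {"small": 1.0, "huge": 500.0}, n_cells=20000, seed=2)
        assert out["huge"] > 0.999


class TestProportionRegression:
    def test_exact_line_recovered(self):
        areas = {"A": 1.0, "B": 2.0, "C": 4.0}
        counts = {e: np.array([10 * a + 5]) for e, a in areas.items()}
        # proportions are exactly linear in area for a single animal
        reg = fit_proportion_regression(
            {e: counts[e] for e in areas}, areas
        )
        total = sum(float(counts[e][0]) for e in areas)
        expected_slope = 10 / total
        assert reg.slope == pytest.approx(expected_slope, rel=1e-9)
        assert reg.intercept == pytest.approx(5 / total, rel=1e-9)

    def test_two_points_fit_exactly(self):
        areas = {"A": 1.0, "D": 3.0}
        reg = fit_proportion_regression(
            {"A": np.array([25]), "D": np.array([75])}, areas
        )
        assert reg.slope == pytest.approx(0.25)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_areas_rejected(self):
        with pytest.raises(ValueError):
            fit_proportion_regression(
                {"A": np.array([5]), "B": np.array([5])}, {"A": 1.0, "B": 1.0}
            )
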