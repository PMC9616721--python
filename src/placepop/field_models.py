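"""Field-formation propensity models: equal-Poisson vs gamma-Poisson.

The equal-Poisson model assumes every place cell forms fields at the same
rate: X ~ Pois(tau * A) with A the environment area (m^2).  The
gamma-Poisson model lets the per-cell propensity vary: T ~ Gamma(alpha,
theta * A), X ~ Pois(T), whose marginal is negative binomial with r =
alpha and p = 1 / (1 + theta * A).  Both are fit by maximum likelihood and
compared with the Bayesian information criterion.  The density-based area
adjustment rescales A by the empirical linear law of field proportion
versus area (rho = (b A + c) / A, A' = A rho / b, i.e. A' = A + c / b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import linregress

__all__ = [
    "EqualPoissonFit",
    "GammaPoissonFit",
    "DensityRegression",
    "gamma_poisson_pmf",
    "gamma_poisson_logpmf",
    "fit_models",
    "adjusted_area",
    "predict_recruitment",
    "fit_proportion_regression",
]


@dataclass(frozen=True)
class EqualPoissonFit:
    """One-parameter Poisson fit: tau is fields per m^2."""

    tau: float
    log_likelihood: float
    bic: float
    n: int


@dataclass(frozen=True)
class GammaPoissonFit:
    """Two-parameter negative-binomial fit: shape alpha, scale theta per m^2."""

    alpha: float
    theta: float
    log_likelihood: float
    bic: float
    n: int


@dataclass(frozen=True)
class DensityRegression:
    """Linear law of per-environment field proportion vs area: y = b A + c."""

    slope: float
    intercept: float
    r: float = float("nan")


def _check_counts(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.integer):
        xf = np.asarray(x, dtype=float)
        if np.any(xf != np.round(xf)):
            raise ValueError("field counts must be integers")
        x = xf.astype(int)
    if np.any(x < 0):
        raise ValueError("field counts must be non-negative")
    return x


def gamma_poisson_logpmf(
    x: np.ndarray, alpha: float, theta: float, area_m2: float
) -> np.ndarray:
    """Log of the gamma-Poisson (negative binomial) PMF, evaluated in log space.

    P(X = x) = Gamma(r + x) / (Gamma(r) Gamma(x + 1)) * p^r * (1 - p)^x
    with r = alpha and p = 1 / (1 + theta * area).
    """
    if alpha <= 0 or theta <= 0 or area_m2 <= 0:
        raise ValueError("alpha, theta and area must be positive")
    x = _check_counts(x)
    r = alpha
    log_p = -np.log1p(theta * area_m2)
    log_1mp = np.log(theta * area_m2) + log_p
    return gammaln(r + x) - gammaln(r) - gammaln(x + 1) + r * log_p + x * log_1mp


def gamma_poisson_pmf(
    x: np.ndarray, alpha: float, theta: float, area_m2: float
) -> np.ndarray:
    return np.exp(gamma_poisson_logpmf(x, alpha, theta, area_m2))


def _poisson_loglik(x: np.ndarray, lam: float) -> float:
    return float(np.sum(x * np.log(lam) - lam - gammaln(x + 1)))


def fit_models(
    counts: np.ndarray, area_m2: float
) -> tuple[EqualPoissonFit, GammaPoissonFit, str]:
    """Fit both propensity models by maximum likelihood; prefer lower BIC.

    Optimisation runs L-BFGS-B on log-transformed parameters; the
    equal-Poisson MLE has the closed form mean(X) / A, which the numeric
    optimum is checked against.  Returns (equal_fit, gamma_fit, preferred)
    with preferred in {"equal_poisson", "gamma_poisson"}.
    """
    x = _check_counts(counts)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 cells to fit")
    if np.all(x == 0):
        raise ValueError("all counts are zero; degenerate likelihood")

    # equal-Poisson: closed form, plus a numeric check
    tau_hat = float(np.mean(x)) / area_m2
    ll_eq = _poisson_loglik(x, tau_hat * area_m2)

    def neg_ll_eq(log_tau: np.ndarray) -> float:
        return -_poisson_loglik(x, np.exp(log_tau[0]) * area_m2)

    res_eq = minimize(neg_ll_eq, [np.log(tau_hat)], method="L-BFGS-B", tol=1e-10)
    if -res_eq.fun > ll_eq + 1e-6:  # pragma: no cover - closed form is optimal
        tau_hat = float(np.exp(res_eq.x[0]))
        ll_eq = float(-res_eq.fun)

    bic_eq = 1 * np.log(n) - 2 * ll_eq
    eq_fit = EqualPoissonFit(tau_hat, ll_eq, float(bic_eq), n)

    # gamma-Poisson: L-BFGS-B on (log alpha, log theta)
    mean, var = float(np.mean(x)), float(np.var(x))
    # moment start: var = m (1 + theta A), alpha theta A = m
    theta0 = max((var / mean - 1.0) / area_m2, 1e-3) if mean > 0 else 0.1
    alpha0 = max(mean / (theta0 * area_m2), 1e-3)

    def neg_ll_gp(params: np.ndarray) -> float:
        a, t = np.exp(params)
        return -float(np.sum(gamma_poisson_logpmf(x, a, t, area_m2)))

    res = minimize(
        neg_ll_gp,
        [np.log(alpha0), np.log(theta0)],
        method="L-BFGS-B",
        bounds=[(-12, 12), (-12, 12)],
        options={"ftol": 1e-12, "gtol": 1e-10},
    )
    alpha_hat, theta_hat = np.exp(res.x)
    ll_gp = float(-res.fun)
    bic_gp = 2 * np.log(n) - 2 * ll_gp
    gp_fit = GammaPoissonFit(float(alpha_hat), float(theta_hat), ll_gp, float(bic_gp), n)

    preferred = "gamma_poisson" if bic_gp < bic_eq else "equal_poisson"
    return eq_fit, gp_fit, preferred


def adjusted_area(area_m2: float, reg: DensityRegression) -> float:
    """Field-density-adjusted environment size A' = A rho / b = A + c / b."""
    if reg.slope <= 0:
        raise ValueError("regression slope must be positive")
    rho = (reg.slope * area_m2 + reg.intercept) / area_m2
    return float(area_m2 * rho / reg.slope)


def fit_proportion_regression(
    field_counts_by_env: dict[str, np.ndarray] | dict[str, list],
    areas_m2: dict[str, float],
) -> DensityRegression:
    """Least-squares line of per-animal field proportion versus area.

    ``field_counts_by_env`` maps env id to an array of per-animal field
    counts (parallel across environments).  Counts are normalised to the
    proportion of each animal's total before fitting.
    """
    envs = sorted(field_counts_by_env)
    if len(envs) < 2:
        raise ValueError("need at least two environments")
    counts = np.array([np.asarray(field_counts_by_env[e], dtype=float) for e in envs])
    areas = np.array([areas_m2[e] for e in envs])
    if np.ptp(areas) == 0:
        raise ValueError("environment areas are degenerate")
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every animal needs at least one field")
    props = counts / totals  # env x animal
    xs = np.repeat(areas, counts.shape[1])
    ys = props.ravel()
    fit = linregress(xs, ys)
    return DensityRegression(float(fit.slope), float(fit.intercept), float(fit.rvalue))


def predict_recruitment(
    fit: GammaPoissonFit,
    areas_m2: dict[str, float],
    reg: DensityRegression | None = None,
    n_cells: int = 100_000,
    seed: int = 0,
) -> dict[str, float]:
    """Per-environment proportion of modelled cells recruited (>= 1 field).

    Draws a propensity tau ~ Gamma(alpha, theta) per modelled cell, then
    per environment a field count ~ Pois(tau * A) (or tau * A' when a
    density regression is given).  Cells with no field in any environment
    are discarded before computing proportions, matching the conditioning
    applied to recorded cells.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = np.random.default_rng(seed)
    envs = sorted(areas_m2)
    taus = rng.gamma(shape=fit.alpha, scale=fit.theta, size=n_cells)
    counts = np.empty((len(envs), n_cells), dtype=np.int64)
    for i, env in enumerate(envs):
        a = areas_m2[env]
        if reg is not None:
            a = adjusted_area(a, reg)
        counts[i] = rng.poisson(taus * a)
    recruited_any = (counts > 0).any(axis=0)
    kept = counts[:, recruited_any]
    if kept.shape[1] == 0:
        return {env: float("nan") for env in envs}
    return {env: float((kept[i] > 0).mean()) for i, env in enumerate(envs)}


def minimum_area_for_recruitment(
    fit: GammaPoissonFit,
    target: float = 0.99,
    n_cells: int = 100_000,
    seed: int = 0,
    area_grid: np.ndarray | None = None,
) -> float:
    """Smallest area (m^2) at which the recruited proportion reaches ``target``.

    Recruitment of a cell with propensity tau in area A is 1 - exp(-tau A);
    the population proportion is averaged over sampled propensities of
    cells with at least one field somewhere (conditioning on the largest
    grid area).
    """
    rng = np.random.default_rng(seed)
    taus = rng.gamma(shape=fit.alpha, scale=fit.theta, size=n_cells)
    if area_grid is None:
        area_grid = np.arange(0.5, 200.0, 0.1)
    # condition on having >= 1 field in the largest considered area
    a_max = float(area_grid[-1])
    weights = 1.0 - np.exp(-taus * a_max)
    denom = weights.sum()
    for a in area_grid:
        prop = float(((1.0 - np.exp(-taus * a)) * weights).sum() / denom)
        if prop >= target:
            return float(a)
    return float("nan")
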