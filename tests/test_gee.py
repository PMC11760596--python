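"""GEE/PGEE against independent oracles (OLS, IRLS logistic, brute SCAD)."""

import warnings

import numpy as np
import pytest
import statsmodels.api as sm

from digiprog.gee import (
    GEEError,
    estimate_working_correlation,
    fit_gee,
    fit_pgee,
    scad_derivative,
    tune_lambda,
)


def _gaussian_clusters(rng, n_clusters=50, size=4, p=4, rho=0.3, beta=None):
    beta = np.zeros(p + 1) if beta is None else beta
    X = np.column_stack([np.ones(n_clusters * size),
                         rng.standard_normal((n_clusters * size, p))])
    b = rng.normal(0, np.sqrt(rho), n_clusters)
    e = rng.normal(0, np.sqrt(1 - rho), (n_clusters, size))
    y = X @ beta + (b[:, None] + e).ravel()
    return X, y, np.repeat(np.arange(n_clusters), size)


def test_independence_gaussian_equals_ols(rng):
    X = np.column_stack([np.ones(40), rng.standard_normal((40, 4))])
    y = X @ np.array([1.0, 2.0, -1.0, 0.5, 0.0]) + rng.standard_normal(40)
    fit = fit_gee(X, y, np.arange(40), family="gaussian", corstr="independence")
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(fit.params, ols, atol=1e-8)


def test_singleton_cluster_logistic_equals_irls(rng):
    X = np.column_stack([np.ones(300), rng.standard_normal((300, 3))])
    p = 1 / (1 + np.exp(-(X @ np.array([0.3, 1.0, -0.7, 0.0]))))
    y = (rng.random(300) < p).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_gee(X, y, np.arange(300), family="binomial",
                      corstr="independence")
        irls = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.params, irls.params, atol=1e-6)


def test_noiseless_response_recovered_exactly(rng):
    X, _, cl = _gaussian_clusters(rng)
    beta = np.array([2.0, 1.0, 0.0, -0.5, 0.25])
    y = X @ beta
    fit = fit_gee(X, y, cl, corstr="exchangeable")
    np.testing.assert_allclose(fit.params, beta, atol=1e-10)


def test_exchangeable_alpha_recovered(rng):
    X, y, cl = _gaussian_clusters(rng, n_clusters=200, size=4, rho=0.5)
    fit = fit_gee(X, y, cl, corstr="exchangeable")
    assert abs(fit.corr.alpha - 0.5) < 0.07


def test_ar1_moment_estimator():
    # AR(1) residual series with known lag-1 correlation
    rng = np.random.default_rng(0)
    rho = 0.6
    n_cl, size = 300, 6
    e = np.zeros((n_cl, size))
    e[:, 0] = rng.standard_normal(n_cl)
    for t in range(1, size):
        e[:, t] = rho * e[:, t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_cl)
    wc = estimate_working_correlation(
        e.ravel(), np.repeat(np.arange(n_cl), size), "ar1")
    assert abs(wc.alpha - rho) < 0.07


def test_alpha_clipped_below_one():
    resid = np.tile([1.0, 1.0, 1.0], 4)
    wc = estimate_working_correlation(resid, np.repeat([0, 1, 2, 3], 3),
                                      "exchangeable")
    assert wc.alpha <= 0.99


def test_size_one_clusters_fall_back_to_independence():
    with pytest.warns(UserWarning, match="independence"):
        wc = estimate_working_correlation(np.ones(5), np.arange(5),
                                          "exchangeable")
    assert wc.kind == "independence"


def test_zero_correlation_residuals():
    rng = np.random.default_rng(1)
    wc = estimate_working_correlation(rng.standard_normal(2000),
                                      np.repeat(np.arange(500), 4),
                                      "exchangeable")
    assert abs(wc.alpha) < 0.05


def test_rank_deficiency_names_columns(rng):
    x = rng.standard_normal(30)
    X = np.column_stack([np.ones(30), x, 2 * x])
    with pytest.raises(GEEError, match="collinear"):
        fit_gee(X, rng.standard_normal(30), np.arange(30),
                column_names=["intercept", "a", "a_doubled"])


def test_scale_equivariance(rng):
    X, y, cl = _gaussian_clusters(rng, beta=np.array([1, 0.5, -0.5, 0, 0.0]))
    fit1 = fit_gee(X, y, cl, corstr="exchangeable")
    Xs = X.copy()
    Xs[:, 1] *= 10.0
    fit2 = fit_gee(Xs, y, cl, corstr="exchangeable")
    np.testing.assert_allclose(fit2.params[1], fit1.params[1] / 10.0,
                               rtol=1e-8)


def test_sandwich_coverage_under_heteroscedasticity():
    """95% robust CIs cover the true slope at close-to-nominal rate even
    with independence working correlation on correlated clusters."""
    rng = np.random.default_rng(7)
    true = 0.8
    hits = 0
    n_sim = 250
    for _ in range(n_sim):
        n_cl, size = 60, 4
        x = rng.standard_normal((n_cl, size))
        b = rng.normal(0, 0.7, n_cl)
        scale = 0.5 + rng.random(n_cl)  # heteroscedastic clusters
        y = 1.0 + true * x + b[:, None] + scale[:, None] * rng.standard_normal(
            (n_cl, size))
        X = np.column_stack([np.ones(n_cl * size), x.ravel()])
        fit = fit_gee(X, y.ravel(), np.repeat(np.arange(n_cl), size),
                      corstr="independence")
        lo, hi = fit.params[1] - 1.96 * fit.bse[1], fit.params[1] + 1.96 * fit.bse[1]
        hits += lo <= true <= hi
    assert 0.90 <= hits / n_sim <= 0.98


# --- SCAD -----------------------------------------------------------------

@pytest.mark.parametrize("theta,lam,a,expected", [
    (0.5, 1.0, 3.7, 1.0),            # first segment returns lambda
    (2.0, 1.0, 3.7, (3.7 - 2) / 2.7),  # 0.62963
    (5.0, 1.0, 3.7, 0.0),            # beyond a*lambda
    (0.0, 0.3, 3.7, 0.3),
])
def test_scad_derivative_segments(theta, lam, a, expected):
    assert scad_derivative(theta, lam, a) == pytest.approx(expected, abs=1e-12)


def test_scad_continuity_and_validation():
    lam, a = 0.7, 3.7
    grid = np.linspace(0, 4 * lam, 2000)
    q = scad_derivative(grid, lam, a)
    assert np.max(np.abs(np.diff(q))) < 2e-3  # continuous in theta
    with pytest.raises(ValueError):
        scad_derivative(1.0, 1.0, a=2.0)
    with pytest.raises(ValueError):
        scad_derivative(-0.1, 1.0)


# --- PGEE -----------------------------------------------------------------

def test_pgee_lambda_zero_equals_gee(rng):
    beta = np.array([1.0, 0.8, 0, 0, 0.5])
    X, y, cl = _gaussian_clusters(rng, beta=beta)
    g = fit_gee(X, y, cl, corstr="exchangeable")
    p = fit_pgee(X, y, cl, corstr="exchangeable", lam=0.0)
    np.testing.assert_allclose(p.params_raw, g.params, atol=1e-6)


def test_pgee_total_shrinkage_empty_support(rng):
    beta = np.array([1.0, 0.8, 0.3, 0, 0])
    X, y, cl = _gaussian_clusters(rng, beta=beta)
    fit = fit_pgee(X, y, cl, corstr="exchangeable", lam=50.0)
    assert fit.support.size == 0


def test_pgee_keeps_unpenalized_covariates(rng):
    beta = np.array([1.0, 0.8, 0, 0, 0])
    X, y, cl = _gaussian_clusters(rng, beta=beta)
    fit = fit_pgee(X, y, cl, corstr="exchangeable", lam=50.0,
                   penalized_index=np.arange(2, 5))
    assert abs(fit.params_raw[1] - 0.8) < 0.2  # column 1 unpenalized


def test_support_size_monotone_in_lambda_on_average():
    lams = (0.02, 0.1, 0.3, 0.7, 1.5)
    sizes = np.zeros(len(lams))
    n_seeds = 20
    for s in range(n_seeds):
        rng = np.random.default_rng(300 + s)
        beta = np.zeros(11)
        beta[1:4] = 0.6
        X, y, cl = _gaussian_clusters(rng, n_clusters=40, p=10, beta=beta)
        for i, lam in enumerate(lams):
            fit = fit_pgee(X, y, cl, corstr="exchangeable", lam=lam)
            sizes[i] += fit.support.size / n_seeds
    assert np.all(np.diff(sizes) <= 1e-9)


def test_tune_lambda_contracts(rng):
    beta = np.array([1.0, 0.8, 0, 0, 0.5])
    X, y, cl = _gaussian_clusters(rng, beta=beta)
    lam, losses = tune_lambda(X, y, cl, lam_grid=(0.25,), seed=0)
    assert lam == 0.25 and losses.shape == (1,)
    with pytest.raises(ValueError):
        tune_lambda(X, y, cl, lam_grid=(), seed=0)


def test_tune_lambda_null_prefers_heavy_penalty():
    grid = (0.01, 0.05, 0.2, 0.5, 1.0)
    big = 0
    n_seeds = 15
    for s in range(n_seeds):
        rng = np.random.default_rng(700 + s)
        X, y, cl = _gaussian_clusters(rng, n_clusters=40, p=8)
        lam, _ = tune_lambda(X, y, cl, lam_grid=grid, seed=s)
        big += lam >= 0.5
    assert big >= 0.8 * n_seeds


def test_tune_lambda_signal_keeps_true_features():
    grid = (0.05, 0.1, 0.2, 0.5, 1.0, 3.0, 10.0)
    ok = 0
    n_seeds = 15
    for s in range(n_seeds):
        rng = np.random.default_rng(900 + s)
        beta = np.zeros(9)
        beta[1:6] = 1.5
        X, y, cl = _gaussian_clusters(rng, n_clusters=60, p=8, beta=beta)
        lam, _ = tune_lambda(X, y, cl, lam_grid=grid, seed=s)
        fit = fit_pgee(X, y, cl, corstr="exchangeable", lam=lam)
        ok += set(range(1, 6)) <= set(fit.support)
    assert ok >= 0.9 * n_seeds
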