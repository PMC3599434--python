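"""The three mapping regressions against exact and brute-force oracles."""

import itertools

import numpy as np
import pytest

import statsmodels.api as sm
from eq5dmap.estimators import (
    BootstrapConfig,
    DegenerateLikelihoodError,
    InsufficientDataError,
    SingularDesignError,
    fit_clad,
    fit_ols_robust,
    fit_quantile,
    fit_tobit,
)


def dummy_design(rng, n, k=4, p=0.3):
    X = np.column_stack([np.ones(n), rng.binomial(1, p, size=(n, k - 1))])
    return X


# ---------------------------------------------------------------------------
# OLS

def test_ols_interpolates_noiseless_data(rng):
    X = dummy_design(rng, 200, k=5)
    beta = np.array([0.9, -0.2, -0.1, -0.3, -0.05])
    fr = fit_ols_robust(X, X @ beta)
    np.testing.assert_allclose(fr.params.to_numpy(), beta, atol=1e-10)
    assert fr.r_squared == pytest.approx(1.0, abs=1e-10)


def test_ols_intercept_only_is_sample_mean(rng):
    y = rng.normal(0.5, 0.2, 101)
    fr = fit_ols_robust(np.ones((101, 1)), y)
    assert fr.params.iloc[0] == pytest.approx(y.mean(), abs=1e-12)


def test_ols_matches_normal_equations_and_hand_hc1(rng):
    """Coefficients match the closed-form solution; HC1 standard errors
    match a hand-built sandwich with n/(n−k) scaling."""
    n, k = 150, 4
    X = dummy_design(rng, n, k=k)
    y = X @ [0.8, -0.2, -0.1, -0.3] + rng.normal(0, 0.2, n) * (1 + X[:, 1])
    fr = fit_ols_robust(X, y)
    beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(fr.params.to_numpy(), beta_hat, atol=1e-10)
    resid = y - X @ beta_hat
    bread = np.linalg.inv(X.T @ X)
    meat = (X * (resid**2)[:, None]).T @ X
    cov_hc1 = n / (n - k) * bread @ meat @ bread
    np.testing.assert_allclose(fr.bse.to_numpy(), np.sqrt(np.diag(cov_hc1)), rtol=1e-8)


def test_ols_rank_deficiency_names_dependent_columns(rng):
    X = dummy_design(rng, 50, k=3)
    X = np.column_stack([X, X[:, 1]])  # duplicate a dummy
    with pytest.raises(SingularDesignError, match="rank deficient"):
        fit_ols_robust(X, rng.normal(size=50))


# ---------------------------------------------------------------------------
# Tobit

def test_tobit_equals_ols_without_censoring(rng):
    X = dummy_design(rng, 400, k=4)
    y = X @ [0.5, -0.2, -0.1, -0.15] + rng.normal(0, 0.1, 400)
    assert (y < 1).all()
    fo, ft = fit_ols_robust(X, y), fit_tobit(X, y)
    np.testing.assert_allclose(ft.params.to_numpy(), fo.params.to_numpy(), atol=1e-4)
    # sigma is the ML (1/n) residual SD
    resid = y - X @ fo.params.to_numpy()
    assert ft.scale_sigma == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-4)


def test_tobit_all_censored_is_degenerate():
    X = np.ones((20, 1))
    with pytest.raises(DegenerateLikelihoodError):
        fit_tobit(X, np.ones(20))


def test_tobit_loglik_path_monotone(small_design):
    X, y = small_design
    fr = fit_tobit(X, y)
    path = fr.diagnostics["nll_path"]
    assert all(b <= a + 1e-8 for a, b in zip(path, path[1:]))
    assert fr.converged


def test_tobit_recovers_censored_latent_model(rng):
    """Moderate-n sanity: right-censored Gaussian data, ~1/3 at the ceiling."""
    n = 4000
    X = dummy_design(rng, n, k=3, p=0.4)
    beta = np.array([0.95, -0.3, -0.2])
    y = np.minimum(X @ beta + rng.normal(0, 0.25, n), 1.0)
    assert 0.15 < np.mean(y >= 1) < 0.5
    fr = fit_tobit(X, y)
    np.testing.assert_allclose(fr.params.to_numpy(), beta, atol=0.05)
    assert fr.scale_sigma == pytest.approx(0.25, abs=0.02)
    assert (fr.ci_lower <= fr.params).all() and (fr.params <= fr.ci_upper).all()


# ---------------------------------------------------------------------------
# Quantile engine

def brute_force_median_fit(X, y):
    """Exhaustive basis-solution oracle: median-regression optima occur at
    exact-fit subsets of k observations; minimise the check loss over all
    such subsets."""
    n, k = X.shape
    best_obj, best_beta = np.inf, None
    for idx in itertools.combinations(range(n), k):
        sub = X[list(idx)]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        beta = np.linalg.solve(sub, y[list(idx)])
        obj = 0.5 * np.sum(np.abs(y - X @ beta))
        if obj < best_obj:
            best_obj, best_beta = obj, beta
    return best_beta, best_obj


def test_quantile_two_points_interpolates():
    X = np.array([[1.0, 0.0], [1.0, 1.0]])
    y = np.array([0.2, 0.9])
    beta = fit_quantile(X, y)
    np.testing.assert_allclose(beta, [0.2, 0.7], atol=1e-9)


def test_quantile_intercept_only_is_median(rng):
    y = rng.normal(0.5, 0.3, 31)
    beta = fit_quantile(np.ones((31, 1)), y)
    assert beta[0] == pytest.approx(np.median(y), abs=1e-9)


def test_quantile_lp_matches_subset_oracle(rng):
    """On 30×3 instances the LP objective equals the exhaustive
    exact-fit-subset optimum."""
    for trial in range(3):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = X @ [0.5, -0.3, 0.2] + rng.standard_t(3, 30) * 0.3
        beta_lp = fit_quantile(X, y, method="lp")
        obj_lp = 0.5 * np.sum(np.abs(y - X @ beta_lp))
        _, obj_bf = brute_force_median_fit(X, y)
        assert obj_lp == pytest.approx(obj_bf, abs=1e-6)


def test_quantile_irls_close_to_lp(rng):
    X = np.column_stack([np.ones(500), rng.binomial(1, 0.3, (500, 2))])
    y = X @ [0.8, -0.2, -0.3] + rng.normal(0, 0.2, 500)
    b_lp = fit_quantile(X, y, method="lp")
    b_irls = fit_quantile(X, y, method="irls")
    obj = lambda b: np.sum(np.abs(y - X @ b))
    assert obj(b_irls) <= obj(b_lp) * (1 + 1e-4)


def test_quantile_tau_quarter_minimises_check_loss(rng):
    y = rng.normal(size=51)
    beta = fit_quantile(np.ones((51, 1)), y, tau=0.25)
    assert beta[0] == pytest.approx(np.quantile(y, 0.25, method="inverted_cdf"), abs=1e-6)


def test_quantile_underdetermined_rejected():
    with pytest.raises(InsufficientDataError):
        fit_quantile(np.ones((2, 3)), np.zeros(2))


# ---------------------------------------------------------------------------
# CLAD

def test_clad_without_ceiling_equals_median_regression(rng):
    X = dummy_design(rng, 120, k=3)
    y = X @ [0.4, -0.2, -0.1] + rng.normal(0, 0.1, 120)
    assert (X @ fit_quantile(X, y) < 1).all()
    fr = fit_clad(X, y)
    np.testing.assert_array_equal(fr.params.to_numpy(), fit_quantile(X, y))
    assert fr.converged and fr.diagnostics["n_iterations"] == 1


def test_clad_intercept_only_below_ceiling_is_median(rng):
    y = rng.uniform(-0.5, 0.9, 41)
    fr = fit_clad(np.ones((41, 1)), y)
    assert fr.params.iloc[0] == pytest.approx(np.median(y), abs=1e-9)


def test_clad_deletes_ceiling_rows(rng):
    # continuous covariate so the fitted median plane extrapolates past the
    # ceiling and the iterative deletion actually fires
    n = 600
    x = rng.uniform(-1, 2, n)
    X = np.column_stack([np.ones(n), x])
    beta = np.array([0.3, 0.5])
    y = np.minimum(X @ beta + rng.normal(0, 0.15, n), 1.0)
    fr = fit_clad(X, y)
    assert fr.diagnostics["n_retained"] < n
    assert fr.diagnostics["n_iterations"] > 1
    np.testing.assert_allclose(fr.params.to_numpy(), beta, atol=0.06)


def test_clad_bootstrap_deterministic_and_brackets(small_design):
    X, y = small_design
    boot = BootstrapConfig(replicates=30, seed=99)
    fr1 = fit_clad(X, y, boot=boot)
    fr2 = fit_clad(X, y, boot=BootstrapConfig(replicates=30, seed=99))
    np.testing.assert_array_equal(fr1.ci_lower.to_numpy(), fr2.ci_lower.to_numpy())
    np.testing.assert_array_equal(fr1.ci_upper.to_numpy(), fr2.ci_upper.to_numpy())
    assert (fr1.ci_lower <= fr1.params).all() and (fr1.params <= fr1.ci_upper).all()
    fr3 = fit_clad(X, y, boot=BootstrapConfig(replicates=30, seed=100))
    assert not np.array_equal(fr1.ci_lower.to_numpy(), fr3.ci_lower.to_numpy())


def test_clad_insufficient_retained_rows():
    X = np.ones((3, 2))
    X[:, 1] = [0.0, 1.0, 2.0]
    with pytest.raises((InsufficientDataError, SingularDesignError)):
        fit_clad(X, np.array([1.0, 1.0, 1.0]), upper=0.0)


def test_bootstrap_config_validation():
    with pytest.raises(ValueError):
        BootstrapConfig(replicates=1)
    with pytest.raises(ValueError):
        BootstrapConfig(ci_method="bca")


def test_fit_result_json_roundtrip(small_design):
    from eq5dmap.estimators import FitResult

    X, y = small_design
    fr = fit_tobit(X, y)
    back = FitResult.from_json(fr.to_json(seed=5))
    np.testing.assert_array_equal(back.params.to_numpy(), fr.params.to_numpy())
    assert back.model_kind == "tobit"
    assert back.scale_sigma == fr.scale_sigma
    assert back.to_json(seed=5) == FitResult.from_json(back.to_json(seed=5)).to_json(seed=5)
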