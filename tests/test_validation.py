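"""Prediction-error metrics, band stratification, cluster test, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eq5dmap.estimators import fit_ols_robust
from eq5dmap.validation import (
    UndefinedTestError,
    ValidationReport,
    ae_fraction,
    band_errors,
    coefficient_correlation,
    error_cluster_test,
    error_metrics,
    validate,
    vif,
)

utility_arrays = hnp.arrays(
    np.float64,
    st.integers(2, 60),
    elements=st.floats(-0.594, 1.0, allow_nan=False),
)


def test_error_metrics_hand_examples():
    assert error_metrics([0.3, 0.7], [0.3, 0.7]) == (0.0, 0.0)
    mae, mse = error_metrics([0.0, 1.0], [0.5, 0.5])
    assert mae == pytest.approx(0.5) and mse == pytest.approx(0.25)


def test_error_metrics_brute_force(rng):
    obs, pred = rng.normal(0.5, 0.3, 100), rng.normal(0.5, 0.3, 100)
    mae, mse = error_metrics(obs, pred)
    assert mae == pytest.approx(sum(abs(o - p) for o, p in zip(obs, pred)) / 100, abs=1e-12)
    assert mse == pytest.approx(sum((o - p) ** 2 for o, p in zip(obs, pred)) / 100, abs=1e-12)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        error_metrics([0.1], [0.1, 0.2])
    with pytest.raises(ValueError, match="mismatch"):
        ae_fraction([0.1], [0.1, 0.2], 0.05)


def test_ae_fraction_strict_inequality():
    assert ae_fraction([0.0, 0.0], [0.04, 0.04], 0.05) == 1.0
    assert ae_fraction([0.0, 0.0], [0.04, 0.06], 0.05) == 0.5
    assert ae_fraction([0.0], [0.05], 0.05) == 0.0  # boundary excluded


def test_band_errors_hand_example():
    bands = band_errors([0.1, 0.6], [0.3, 0.6])
    assert bands["0.00-0.24"] == (pytest.approx(-0.2), 1)
    assert bands["0.50-0.74"] == (pytest.approx(0.0), 1)
    assert bands["<0"] is None  # empty band flagged absent, not zero


def test_band_errors_brute_force_partition(rng):
    obs = rng.uniform(-0.594, 1.0, 500)
    pred = obs + rng.normal(0, 0.1, 500)
    bands = band_errors(obs, pred)
    edges = [(-np.inf, 0.0), (0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0 + 1e-12)]
    for (label, got), (lo, hi) in zip(bands.items(), edges):
        mask = (obs >= lo) & (obs < hi)
        expected = (obs - pred)[mask]
        if expected.size == 0:
            assert got is None
        else:
            assert got[0] == pytest.approx(expected.mean(), abs=1e-12)
            assert got[1] == expected.size
    # observation at exactly 1 belongs to the top band
    assert band_errors([1.0], [0.9])["0.75-1"] == (pytest.approx(0.1), 1)


@given(obs=utility_arrays, shift=st.floats(-0.3, 0.3, allow_nan=False))
def test_band_means_aggregate_to_overall_mean(obs, shift):
    pred = np.clip(obs + shift, -2, 2)
    bands = band_errors(obs, pred)
    total, count = 0.0, 0
    for v in bands.values():
        if v is not None:
            total += v[0] * v[1]
            count += v[1]
    assert count == len(obs)
    assert total / count == pytest.approx(float(np.mean(obs - pred)), abs=1e-9)


@given(obs=utility_arrays, noise=st.floats(0.0, 0.5))
def test_metric_identities(obs, noise):
    pred = obs + noise
    mae, mse = error_metrics(obs, pred)
    assert mse >= mae**2 - 1e-12  # Jensen
    assert ae_fraction(obs, pred, 0.05) <= ae_fraction(obs, pred, 0.10) + 1e-12


def test_cluster_test_identical_groups_p_one():
    obs = np.array([0.2, 0.3, 0.7, 0.8])
    err = np.array([0.1, -0.1, 0.1, -0.1])
    assert error_cluster_test(obs, obs - err) == pytest.approx(1.0)


def test_cluster_test_detects_strong_separation(rng):
    obs = np.concatenate([rng.uniform(0, 0.45, 100), rng.uniform(0.55, 1.0, 100)])
    err = np.where(obs < 0.5, -0.26, 0.0) + rng.normal(0, 0.02, 200)
    p = error_cluster_test(obs, obs - err)
    assert p < 1e-10


def test_cluster_test_undefined_cases():
    with pytest.raises(UndefinedTestError, match="≥2"):
        error_cluster_test([0.2, 0.7, 0.8], [0.2, 0.7, 0.8])
    # exactly representable values so within-group variances are exactly zero
    with pytest.raises(UndefinedTestError, match="variance"):
        error_cluster_test([0.25, 0.375, 0.75, 1.0], [0.0, 0.125, 0.75, 1.0])


def test_vif_orthogonal_columns_are_one(rng):
    n = 64
    X = np.column_stack([np.ones(n), np.tile([1, -1], n // 2), np.repeat([1, -1], n // 2)])
    v = vif(X)
    assert v.to_numpy() == pytest.approx([1.0, 1.0], abs=1e-10)


def test_vif_duplicated_column_infinite(rng):
    x = rng.binomial(1, 0.4, 80).astype(float)
    X = np.column_stack([np.ones(80), x, x])
    v = vif(X)
    assert np.isinf(v.iloc[0]) and np.isinf(v.iloc[1])


def test_vif_two_regressor_closed_form(rng):
    """With two regressors, VIF = 1/(1−ρ²) for their sample correlation."""
    n = 400
    a = rng.normal(size=n)
    b = 0.7 * a + rng.normal(0, 0.6, n)
    X = pd.DataFrame({"const": np.ones(n), "a": a, "b": b})
    rho = np.corrcoef(a, b)[0, 1]
    v = vif(X)
    assert v["a"] == pytest.approx(1 / (1 - rho**2), rel=1e-9)
    assert v["b"] == pytest.approx(1 / (1 - rho**2), rel=1e-9)


def test_coefficient_correlation_cases(rng, small_design):
    from eq5dmap.estimators import FitResult

    def fit_with_cov(cov):
        names = [f"b{i}" for i in range(cov.shape[0])]
        p = pd.Series(np.zeros(cov.shape[0]), index=names)
        return FitResult("ols", p, p, p, 0.5, 10, True,
                         cov_params=pd.DataFrame(cov, index=names, columns=names))

    corr = coefficient_correlation(fit_with_cov(np.diag([1.0, 4.0, 9.0])))
    np.testing.assert_allclose(corr.to_numpy(), np.eye(3), atol=1e-12)
    corr2 = coefficient_correlation(fit_with_cov(np.array([[4.0, 2.0], [2.0, 4.0]])))
    assert corr2.iloc[0, 1] == pytest.approx(0.5)
    A = rng.normal(size=(4, 4))
    spd = A @ A.T + 4 * np.eye(4)
    corr3 = coefficient_correlation(fit_with_cov(spd)).to_numpy()
    sd = np.sqrt(np.diag(spd))
    np.testing.assert_allclose(corr3, spd / np.outer(sd, sd), atol=1e-12)
    np.testing.assert_allclose(corr3, corr3.T, atol=1e-15)

    X, y = small_design
    with pytest.raises(ValueError, match="covariance"):
        from eq5dmap.estimators import fit_clad

        coefficient_correlation(fit_clad(X, y))  # no bootstrap → no covariance


def test_validation_report_roundtrip_and_invariants(rng):
    obs = rng.uniform(-0.5, 1.0, 120)
    pred = obs + rng.normal(0, 0.15, 120)
    report = validate(obs, pred, model_kind="ols")
    back = ValidationReport.from_json(report.to_json())
    assert back.to_json() == report.to_json()
    table = report.render_table()
    assert "MAE" in table and "0.75-1" in table
    with pytest.raises(ValueError, match="MSE"):
        ValidationReport(
            n=2, mean_obs=0, sd_obs=0, min_obs=0, max_obs=0,
            mean_pred=0, sd_pred=0, min_pred=0, max_pred=0,
            mae=0.5, mse=0.1, frac_ae_lt_005=0.2, frac_ae_lt_010=0.4,
        )
    with pytest.raises(ValueError, match="exceed"):
        ValidationReport(
            n=2, mean_obs=0, sd_obs=0, min_obs=0, max_obs=0,
            mean_pred=0, sd_pred=0, min_pred=0, max_pred=0,
            mae=0.1, mse=0.05, frac_ae_lt_005=0.6, frac_ae_lt_010=0.4,
        )


def test_perfect_predictions_give_zero_errors():
    obs = [0.2, 0.5, 0.9]
    report = validate(obs, obs)
    assert report.mae == 0.0 and report.mse == 0.0
    assert report.frac_ae_lt_005 == 1.0


def test_plots_return_axes(rng, tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from eq5dmap.validation import plot_errors, plot_scatter

    obs = rng.uniform(0, 1, 50)
    pred = obs + rng.normal(0, 0.1, 50)
    ax1 = plot_scatter(obs, pred, model_kind="ols")
    ax2 = plot_errors(obs, pred)
    assert ax1.get_xlabel() == "Observed EQ-5D weight"
    assert "error" in ax2.get_ylabel().lower()
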