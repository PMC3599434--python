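"""Prediction-accuracy battery and multicollinearity diagnostics.

The mapping literature judges a crosswalk on out-of-sample prediction
error: mean absolute error (MAE), mean squared error (MSE, sensitive to
both bias and spread), and the fraction of patients whose absolute error
stays under 0.05 or 0.10 utility. Because mapping errors are known to
concentrate in worse health states, the battery also stratifies the mean
error (observed − predicted, so overprediction is negative) by bands of
the observed utility and tests whether errors differ between observations
below and above utility 0.5 (Welch two-sample test). Design-side
diagnostics (variance inflation factors, coefficient correlations) flag
multicollinearity among the dummies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import FitResult

__all__ = [
    "BANDS",
    "ValidationReport",
    "error_metrics",
    "ae_fraction",
    "band_errors",
    "error_cluster_test",
    "vif",
    "coefficient_correlation",
    "validate",
]


class UndefinedTestError(ValueError):
    """The cluster test is undefined (group too small or zero variance)."""


#: Observed-utility bands: half-open on the left bands, closed at 1 on top.
BANDS = (
    ("<0", -np.inf, 0.0),
    ("0.00-0.24", 0.0, 0.25),
    ("0.25-0.49", 0.25, 0.5),
    ("0.50-0.74", 0.5, 0.75),
    ("0.75-1", 0.75, np.nextafter(1.0, 2.0)),
)


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape[0]} observed vs {pred.shape[0]} predicted")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return obs, pred


def error_metrics(observed, predicted) -> tuple[float, float]:
    """(MAE, MSE) between observed and predicted utilities."""
    obs, pred = _pair(observed, predicted)
    err = obs - pred
    return float(np.mean(np.abs(err))), float(np.mean(err * err))


def ae_fraction(observed, predicted, threshold: float) -> float:
    """Fraction of absolute errors strictly below ``threshold``."""
    obs, pred = _pair(observed, predicted)
    return float(np.mean(np.abs(obs - pred) < threshold))


def band_errors(observed, predicted) -> dict[str, Optional[tuple[float, int]]]:
    """Mean error (observed − predicted) within observed-utility bands.

    Bands: (−∞, 0), [0, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1].
    Returns ``{label: (mean_error, count)}`` with ``None`` for an empty
    band (absent, not zero).
    """
    obs, pred = _pair(observed, predicted)
    err = obs - pred
    out: dict[str, Optional[tuple[float, int]]] = {}
    for label, lo, hi in BANDS:
        mask = (obs >= lo) & (obs < hi)
        out[label] = (float(err[mask].mean()), int(mask.sum())) if mask.any() else None
    return out


def error_cluster_test(observed, predicted, cutoff: float = 0.5) -> float:
    """Welch test for error clustering below vs. above an observed-utility cutoff.

    Splits the sample at ``observed < cutoff`` and compares the mean error
    (observed − predicted) between the two groups with a two-sided Welch
    (unequal-variance) two-sample t test; returns the p-value.

    Raises :class:`UndefinedTestError` if either group has fewer than two
    members or the pooled variance is zero.
    """
    obs, pred = _pair(observed, predicted)
    err = obs - pred
    low, high = err[obs < cutoff], err[obs >= cutoff]
    if len(low) < 2 or len(high) < 2:
        raise UndefinedTestError(
            f"cluster test needs ≥2 observations per group (got {len(low)}/{len(high)})"
        )
    if np.var(low, ddof=1) + np.var(high, ddof=1) == 0:
        if np.mean(low) == np.mean(high):
            return 1.0
        raise UndefinedTestError("zero within-group variance with unequal means")
    t = stats.ttest_ind(low, high, equal_var=False)
    return float(t.pvalue)


def vif(X) -> pd.Series:
    """Variance inflation factors for every non-intercept design column.

    ``VIF_j = 1/(1 − R²_j)`` from regressing column j on the remaining
    columns (intercept included). Exactly collinear columns report ``inf``.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    is_const = [np.ptp(Xa[:, j]) == 0 for j in range(Xa.shape[1])]
    out = {}
    for j in range(Xa.shape[1]):
        if is_const[j]:
            continue  # the intercept target column has no VIF
        others = np.delete(Xa, j, axis=1)
        if not any(is_const[i] for i in range(Xa.shape[1]) if i != j):
            others = np.column_stack([np.ones(len(Xa)), others])
        yj = Xa[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
        out[names[j]] = np.inf if 1.0 - r2 <= 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def coefficient_correlation(fit: FitResult) -> pd.DataFrame:
    """Correlation matrix of the coefficient estimates.

    Normalises the fit's coefficient covariance to correlations
    (symmetric, unit diagonal). Raises if the fit carries no covariance
    estimate (e.g. CLAD without a bootstrap).
    """
    if fit.cov_params is None:
        raise ValueError(
            f"{fit.model_kind} fit carries no coefficient covariance estimate"
        )
    cov = fit.cov_params.to_numpy(dtype=float)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=fit.cov_params.index, columns=fit.cov_params.columns)


@dataclass
class ValidationReport:
    """Predicted-vs-observed summary in the layout of the published table.

    ``band_mean_errors`` maps band label → mean(observed − predicted), or
    ``None`` for an empty band; ``band_counts`` carries the band sizes.
    ``cluster_test_p`` is ``None`` when the test is undefined on the data.
    """

    n: int
    mean_obs: float
    sd_obs: float
    min_obs: float
    max_obs: float
    mean_pred: float
    sd_pred: float
    min_pred: float
    max_pred: float
    mae: float
    mse: float
    frac_ae_lt_005: float
    frac_ae_lt_010: float
    band_mean_errors: dict = field(default_factory=dict)
    band_counts: dict = field(default_factory=dict)
    cluster_test_p: Optional[float] = None
    model_kind: str = ""

    def __post_init__(self) -> None:
        if self.mae < 0 or self.mse < self.mae**2 - 1e-12:
            raise ValueError("inconsistent error metrics (need MSE ≥ MAE²)")
        for frac in (self.frac_ae_lt_005, self.frac_ae_lt_010):
            if not 0 <= frac <= 1:
                raise ValueError("AE fractions must lie in [0, 1]")
        if self.frac_ae_lt_005 > self.frac_ae_lt_010 + 1e-12:
            raise ValueError("AE<0.05 fraction cannot exceed AE<0.10 fraction")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "n", "mean_obs", "sd_obs", "min_obs", "max_obs",
            "mean_pred", "sd_pred", "min_pred", "max_pred",
            "mae", "mse", "frac_ae_lt_005", "frac_ae_lt_010",
            "band_mean_errors", "band_counts", "cluster_test_p", "model_kind",
        )}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls(**json.loads(text))

    def render_table(self) -> str:
        """Plain-text table mirroring the published validation layout."""
        hdr = f"{'Model':<10}{'Mean':>8}{'SD':>8}{'Min':>8}{'Max':>8}{'MAE':>8}{'MSE':>8}{'AE<0.05':>9}{'AE<0.10':>9}"
        obs = (f"{'Observed':<10}{self.mean_obs:>8.3f}{self.sd_obs:>8.3f}"
               f"{self.min_obs:>8.3f}{self.max_obs:>8.3f}{'n/a':>8}{'n/a':>8}{'n/a':>9}{'n/a':>9}")
        prd = (f"{self.model_kind.upper() or 'Predicted':<10}{self.mean_pred:>8.3f}{self.sd_pred:>8.3f}"
               f"{self.min_pred:>8.3f}{self.max_pred:>8.3f}{self.mae:>8.3f}{self.mse:>8.3f}"
               f"{self.frac_ae_lt_005:>8.0%}{self.frac_ae_lt_010:>8.0%}")
        lines = [f"Validation (n = {self.n})", hdr, obs, prd, "", "Mean error by observed-utility band:"]
        for label, _, _ in BANDS:
            mean = self.band_mean_errors.get(label)
            cnt = self.band_counts.get(label, 0)
            lines.append(
                f"  {label:<10} " + ("(empty)" if mean is None else f"{mean:+.2f}  (n={cnt})")
            )
        if self.cluster_test_p is not None:
            lines.append(f"Error clustering below vs. above 0.5: P = {self.cluster_test_p:.4g}")
        return "\n".join(lines)


def validate(observed, predicted, model_kind: str = "") -> ValidationReport:
    """Full prediction-accuracy report for one model on one sample."""
    obs, pred = _pair(observed, predicted)
    mae, mse = error_metrics(obs, pred)
    bands = band_errors(obs, pred)
    try:
        p = error_cluster_test(obs, pred)
    except UndefinedTestError:
        p = None
    return ValidationReport(
        n=len(obs),
        mean_obs=float(obs.mean()), sd_obs=float(obs.std(ddof=1)) if len(obs) > 1 else 0.0,
        min_obs=float(obs.min()), max_obs=float(obs.max()),
        mean_pred=float(pred.mean()), sd_pred=float(pred.std(ddof=1)) if len(pred) > 1 else 0.0,
        min_pred=float(pred.min()), max_pred=float(pred.max()),
        mae=mae, mse=mse,
        frac_ae_lt_005=ae_fraction(obs, pred, 0.05),
        frac_ae_lt_010=ae_fraction(obs, pred, 0.10),
        band_mean_errors={k: (None if v is None else v[0]) for k, v in bands.items()},
        band_counts={k: (0 if v is None else v[1]) for k, v in bands.items()},
        cluster_test_p=p,
        model_kind=model_kind,
    )


def plot_scatter(observed, predicted, ax=None, model_kind: str = ""):
    """Observed vs. predicted weights with the identity diagonal."""
    import matplotlib.pyplot as plt

    obs, pred = _pair(observed, predicted)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(obs, pred, s=12, alpha=0.6, edgecolors="none")
    lims = (-0.65, 1.05)
    ax.plot(lims, lims, color="grey", lw=1, ls="--")
    ax.set_xlim(lims); ax.set_ylim(lims)
    ax.set_xlabel("Observed EQ-5D weight")
    ax.set_ylabel(f"Predicted EQ-5D weight{f' ({model_kind.upper()})' if model_kind else ''}")
    return ax


def plot_errors(observed, predicted, ax=None, model_kind: str = ""):
    """Prediction error (observed − predicted) against the observed weight."""
    import matplotlib.pyplot as plt

    obs, pred = _pair(observed, predicted)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(obs, obs - pred, s=12, alpha=0.6, edgecolors="none")
    ax.axhline(0, color="grey", lw=1, ls="--")
    ax.axvline(0.5, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("Observed EQ-5D weight")
    ax.set_ylabel(f"Prediction error{f' ({model_kind.upper()})' if model_kind else ''}")
    return ax
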