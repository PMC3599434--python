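"""The three mapping regressions: OLS (robust SEs), right-censored Tobit, CLAD.

All three regress an EQ-5D utility on the same dummy design matrix; they
differ in how they treat the ceiling of the utility scale at 1.

* **OLS** ignores the ceiling; heteroscedasticity-consistent (HC1)
  standard errors adjust the inference, not the point estimates.
* **Tobit** maximises the right-censored Gaussian likelihood: rows at the
  ceiling contribute the upper-tail probability P(latent ≥ 1 | x), the
  rest the Gaussian density of their residual at scale σ.
* **CLAD** (censored least absolute deviation, Powell's estimator) is the
  median-regression analogue, consistent under non-normal and
  heteroscedastic errors with conditional median zero. It is fitted by
  iterative deletion: fit a median regression, drop observations whose
  fitted value exceeds the ceiling, refit, repeat until the retained set
  stabilises. Confidence intervals come from a nonparametric percentile
  bootstrap that re-runs the whole iteration per replicate.

The median-regression engine (`fit_quantile`) solves the check-loss
minimisation either as an exact linear programme (small problems) or via
statsmodels' iteratively reweighted least squares (large problems).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.tools import numdiff

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "BootstrapConfig",
    "SingularDesignError",
    "DegenerateLikelihoodError",
    "InsufficientDataError",
    "fit_ols_robust",
    "fit_tobit",
    "fit_quantile",
    "fit_clad",
]

#: Row count above which `fit_quantile(method="auto")` switches from the
#: exact LP to IRLS.
_LP_MAX_ROWS = 2000


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""


class DegenerateLikelihoodError(ValueError):
    """The censored likelihood carries no information (e.g. all rows censored)."""


class InsufficientDataError(ValueError):
    """Too few rows remain to identify the coefficients."""


@dataclass(frozen=True)
class BootstrapConfig:
    """Nonparametric bootstrap settings for CLAD confidence intervals."""

    replicates: int = 1000
    ci_method: str = "percentile"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("bootstrap needs at least 2 replicates")
        if self.ci_method != "percentile":
            raise ValueError(f"unsupported ci_method {self.ci_method!r}")


@dataclass
class FitResult:
    """Uniform result of one mapping regression.

    ``params``/``ci_lower``/``ci_upper`` are aligned, named Series in the
    frozen coefficient order. ``scale_sigma`` is the latent-error SD
    (Tobit only). ``r_squared`` is the ordinary R² for OLS and a declared
    pseudo-R² otherwise. ``cov_params`` holds the coefficient covariance
    where an estimate exists (robust sandwich for OLS, inverse observed
    information for Tobit, bootstrap covariance for CLAD when run with a
    bootstrap). ``diagnostics`` is a free-form iteration log.
    """

    model_kind: str
    params: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    r_squared: float
    n_used: int
    converged: bool
    scale_sigma: Optional[float] = None
    bse: Optional[pd.Series] = None
    cov_params: Optional[pd.DataFrame] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale_sigma is not None and not self.scale_sigma > 0:
            raise ValueError("scale_sigma must be positive")
        bad = (self.ci_lower > self.params + 1e-12) | (self.ci_upper < self.params - 1e-12)
        if bool(bad.any()):
            raise ValueError("confidence bounds must bracket the point estimates")

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame({"lower": self.ci_lower, "upper": self.ci_upper})

    def to_json(self, **settings) -> str:
        """Serialize to a stable JSON layout (bit-stable for fixed inputs)."""
        payload = {
            "model_kind": self.model_kind,
            "coefficient_names": list(self.params.index),
            "coefficients": [float(v) for v in self.params],
            "ci_lower": [float(v) for v in self.ci_lower],
            "ci_upper": [float(v) for v in self.ci_upper],
            "scale_sigma": self.scale_sigma,
            "r_squared": self.r_squared,
            "n_used": self.n_used,
            "converged": self.converged,
            "provenance": settings,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        names = d["coefficient_names"]
        return cls(
            model_kind=d["model_kind"],
            params=pd.Series(d["coefficients"], index=names),
            ci_lower=pd.Series(d["ci_lower"], index=names),
            ci_upper=pd.Series(d["ci_upper"], index=names),
            scale_sigma=d.get("scale_sigma"),
            r_squared=d["r_squared"],
            n_used=d["n_used"],
            converged=d["converged"],
            diagnostics={"provenance": d.get("provenance", {})},
        )


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError(f"X has {Xa.shape[0]} rows but y has {ya.shape[0]}")
    return Xa, ya, names


def _check_rank(Xa: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        # QR with pivoting: columns pivoted beyond the numerical rank are
        # linearly dependent on the preceding ones.
        from scipy.linalg import qr

        _, R, piv = qr(Xa, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xa.shape) * np.finfo(float).eps if diag.size else 0.0
        dependent = [names[j] for j in piv[np.sum(diag > tol):]]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {Xa.shape[1]}); "
            f"dependent columns: {dependent}"
        )


# ---------------------------------------------------------------------------
# OLS with robust standard errors

def fit_ols_robust(X, y) -> FitResult:
    """OLS with heteroscedasticity-consistent (HC1) standard errors.

    Point estimates are the ordinary least-squares coefficients; the HC1
    sandwich (with n/(n−k) small-sample scaling) adjusts the variance
    only. 95% confidence intervals use the t distribution with n−k
    degrees of freedom.
    """
    Xa, ya, names = _as_xy(X, y)
    _check_rank(Xa, names)
    res = sm.OLS(ya, Xa).fit(cov_type="HC1", use_t=True)
    ci = res.conf_int(alpha=0.05)
    return FitResult(
        model_kind="ols",
        params=pd.Series(res.params, index=names),
        ci_lower=pd.Series(ci[:, 0], index=names),
        ci_upper=pd.Series(ci[:, 1], index=names),
        bse=pd.Series(res.bse, index=names),
        cov_params=pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names),
        r_squared=float(res.rsquared),
        n_used=int(res.nobs),
        converged=True,
        diagnostics={"cov_type": "HC1", "df_resid": float(res.df_resid)},
    )


# ---------------------------------------------------------------------------
# Tobit (right-censored Gaussian MLE)

def _tobit_nll_grad(theta, Xa, ya, upper, cens):
    """Negative log-likelihood and gradient in (beta, log sigma)."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    xb = Xa @ beta
    n = len(ya)
    ll = np.empty(n)
    # uncensored: Gaussian density of the residual
    r = (ya[~cens] - xb[~cens]) / sigma
    ll_unc = -0.5 * np.log(2 * np.pi) - log_sigma - 0.5 * r * r
    # censored at the ceiling: upper-tail probability of the latent value
    z = (upper - xb[cens]) / sigma
    ll_cens = stats.norm.logsf(z)
    ll[~cens], ll[cens] = ll_unc, ll_cens

    grad = np.zeros(len(theta))
    # hazard of the standard normal at z, computed in log space for stability
    lam = np.exp(stats.norm.logpdf(z) - stats.norm.logsf(z))
    grad[:-1] = (Xa[~cens].T @ (r / sigma)) + (Xa[cens].T @ (lam / sigma))
    grad[-1] = np.sum(-1.0 + r * r) + np.sum(lam * z)
    return -np.sum(ll), -grad


def _tobit_loglike(theta, Xa, ya, upper, cens) -> float:
    return -_tobit_nll_grad(theta, Xa, ya, upper, cens)[0]


def fit_tobit(X, y, upper: float = 1.0, gtol: float = 1e-8, maxiter: int = 500) -> FitResult:
    """Right-censored Tobit by maximum likelihood.

    Observations with ``y >= upper`` are treated as censored at the
    ceiling. Starting values are the OLS fit; the likelihood is maximised
    by BFGS on (β, log σ) with an analytic gradient. 95% CIs are normal
    intervals from the inverse observed information at the optimum.
    The pseudo-R² is the likelihood-ratio (McFadden) statistic against a
    censored intercept-only null.
    """
    Xa, ya, names = _as_xy(X, y)
    _check_rank(Xa, names)
    cens = ya >= upper - 1e-12
    if cens.all():
        raise DegenerateLikelihoodError("all observations censored at the ceiling; "
                                        "the likelihood carries no information")
    # start from OLS on all rows; residual SD of the uncensored rows
    beta0, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
    resid = ya - Xa @ beta0
    sigma0 = max(np.std(resid[~cens]), 1e-3)
    theta0 = np.append(beta0, np.log(sigma0))

    nll_path: list[float] = []
    n = len(ya)

    # optimise the mean nll so the gradient tolerance is per-observation
    def fun(t):
        f, g = _tobit_nll_grad(t, Xa, ya, upper, cens)
        return f / n, g / n

    def cb(tk):
        nll_path.append(_tobit_nll_grad(tk, Xa, ya, upper, cens)[0])

    opt = optimize.minimize(
        fun, theta0, jac=True, method="BFGS", callback=cb,
        options={"gtol": gtol, "maxiter": maxiter},
    )
    # BFGS can stop on line-search precision loss with the gradient already
    # far below any useful tolerance; accept such points
    grad_inf = float(np.max(np.abs(opt.jac)))
    success = bool(opt.success) or grad_inf < 1e-6
    theta = opt.x
    beta, sigma = theta[:-1], float(np.exp(theta[-1]))
    llf = -float(opt.fun) * n

    # observed information in the (beta, sigma) parameterisation
    def nll_direct(t):
        t2 = np.append(t[:-1], np.log(max(t[-1], 1e-12)))
        return _tobit_nll_grad(t2, Xa, ya, upper, cens)[0]

    H = numdiff.approx_hess(np.append(beta, sigma), nll_direct)
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular information
        cov_full = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov_full), 0, None))
    zcrit = stats.norm.ppf(0.975)

    # censored intercept-only null for the likelihood-ratio pseudo-R²
    ones = np.ones((len(ya), 1))
    b0 = np.array([np.mean(ya)])
    s0 = max(np.std(ya - np.mean(ya)), 1e-3)
    def fun0(t):
        f, g = _tobit_nll_grad(t, ones, ya, upper, cens)
        return f / n, g / n

    opt0 = optimize.minimize(
        fun0, np.append(b0, np.log(s0)), jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    llnull = -float(opt0.fun) * n
    pseudo_r2 = 1.0 - llf / llnull if llnull != 0 else np.nan

    return FitResult(
        model_kind="tobit",
        params=pd.Series(beta, index=names),
        ci_lower=pd.Series(beta - zcrit * se[:-1], index=names),
        ci_upper=pd.Series(beta + zcrit * se[:-1], index=names),
        bse=pd.Series(se[:-1], index=names),
        cov_params=pd.DataFrame(cov_full[:-1, :-1], index=names, columns=names),
        scale_sigma=sigma,
        r_squared=float(pseudo_r2),
        n_used=len(ya),
        converged=success,
        diagnostics={
            "loglike": llf,
            "loglike_null": llnull,
            "n_censored": int(cens.sum()),
            "nll_path": nll_path,
            "optimizer_message": str(opt.message),
            "gradient_inf_norm": grad_inf,
            "sigma_se": float(se[-1]),
        },
    )


# ---------------------------------------------------------------------------
# Quantile regression engine

def _check_loss(resid: np.ndarray, tau: float) -> float:
    return float(np.sum(resid * (tau - (resid < 0))))


def fit_quantile(X, y, tau: float = 0.5, method: str = "auto") -> np.ndarray:
    """Linear quantile regression: minimise the check loss Σ ρ_tau(y − Xβ).

    At ``tau=0.5`` this is median regression (half the sum of absolute
    residuals). ``method="lp"`` solves the exact linear programme with
    HiGHS; ``method="irls"`` uses statsmodels' iteratively reweighted
    least squares; ``"auto"`` picks the LP for small problems
    (n ≤ 2000) and IRLS above.

    Returns the coefficient vector (numpy array in column order).
    """
    Xa, ya, names = _as_xy(X, y)
    n, k = Xa.shape
    if n < k:
        raise InsufficientDataError(f"{n} rows cannot identify {k} coefficients")
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    if method == "auto":
        method = "lp" if n <= _LP_MAX_ROWS else "irls"
    if method == "lp":
        # variables: beta (free), u = positive residual part, v = negative part
        c = np.concatenate([np.zeros(k), tau * np.ones(n), (1 - tau) * np.ones(n)])
        A = sp.hstack([sp.csr_matrix(Xa), sp.eye(n), -sp.eye(n)], format="csc")
        bounds = [(None, None)] * k + [(0, None)] * (2 * n)
        res = optimize.linprog(c, A_eq=A, b_eq=ya, bounds=bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"quantile LP failed: {res.message}")
        return res.x[:k]
    if method == "irls":
        qr = sm.QuantReg(ya, Xa).fit(q=tau, p_tol=1e-9, max_iter=5000)
        return np.asarray(qr.params)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# CLAD (Powell's censored least absolute deviation)

def _clad_point(Xa, ya, upper, method, max_iter=100):
    """Iterative-deletion CLAD point estimate.

    Returns (beta, converged, n_iter, retained_mask, objective, path)
    where objective = Σ_i |y_i − min(x_i β, upper)| over all rows.
    """
    n, k = Xa.shape
    retained = np.ones(n, dtype=bool)
    seen: dict[bytes, int] = {}
    best_beta, best_obj, best_mask = None, np.inf, None
    converged = False
    path = []
    for it in range(max_iter):
        if retained.sum() < k:
            raise InsufficientDataError(
                f"retained set shrank to {int(retained.sum())} rows (< {k} coefficients)"
            )
        beta = fit_quantile(Xa[retained], ya[retained], 0.5, method=method)
        fitted = Xa @ beta
        obj = float(np.sum(np.abs(ya - np.minimum(fitted, upper))))
        path.append({"iter": it, "n_retained": int(retained.sum()), "objective": obj})
        if obj < best_obj:
            best_beta, best_obj, best_mask = beta, obj, retained.copy()
        new_retained = fitted <= upper
        if np.array_equal(new_retained, retained):
            converged = True
            best_beta, best_obj, best_mask = beta, obj, retained
            break
        key = np.packbits(new_retained).tobytes()
        if key in seen:
            logger.warning("CLAD retained-set cycle detected at iteration %d", it)
            break
        seen[key] = it
        retained = new_retained
    return best_beta, converged, len(path), best_mask, best_obj, path


def fit_clad(
    X,
    y,
    upper: float = 1.0,
    boot: Optional[BootstrapConfig] = None,
    method: str = "auto",
    max_iter: int = 100,
) -> FitResult:
    """Censored least absolute deviation (Powell) via iterative deletion.

    Approximates the minimiser of Σ|y_i − min(x_i β, upper)|: fit a median
    regression on the current subsample, drop rows whose fitted value
    exceeds the ceiling, refit, and repeat until the retained set
    stabilises (or a cycle / the iteration cap is hit, in which case the
    best-objective iterate is returned with ``converged=False``).

    Confidence intervals, when ``boot`` is given, are percentile bootstrap
    intervals re-running the full iteration on each resample; without a
    bootstrap the CIs degenerate to the point estimates and carry no
    inferential content. The pseudo-R² is
    ``1 − Σ|resid| / Σ|y − median(y)|`` over the retained rows.
    """
    Xa, ya, names = _as_xy(X, y)
    _check_rank(Xa, names)
    beta, converged, n_iter, mask, obj, path = _clad_point(Xa, ya, upper, method, max_iter)

    resid_ret = ya[mask] - np.minimum(Xa[mask] @ beta, upper)
    denom = float(np.sum(np.abs(ya[mask] - np.median(ya[mask]))))
    pseudo_r2 = 1.0 - float(np.sum(np.abs(resid_ret))) / denom if denom > 0 else np.nan

    cov = None
    bse = None
    if boot is not None:
        rng = np.random.default_rng(boot.seed)
        n = len(ya)
        draws = np.empty((boot.replicates, Xa.shape[1]))
        n_failed = 0
        for b in range(boot.replicates):
            idx = rng.integers(0, n, size=n)
            try:
                draws[b], *_ = _clad_point(Xa[idx], ya[idx], upper, method, max_iter)
            except (InsufficientDataError, RuntimeError):
                draws[b] = np.nan
                n_failed += 1
        ok = draws[~np.isnan(draws).any(axis=1)]
        lo = np.percentile(ok, 2.5, axis=0)
        hi = np.percentile(ok, 97.5, axis=0)
        # percentile bounds can fail to bracket a point estimate in tiny
        # samples; widen to include it so the interval stays honest
        lo = np.minimum(lo, beta)
        hi = np.maximum(hi, beta)
        cov = pd.DataFrame(np.cov(ok, rowvar=False), index=names, columns=names)
        bse = pd.Series(ok.std(axis=0, ddof=1), index=names)
    else:
        lo = hi = beta

    return FitResult(
        model_kind="clad",
        params=pd.Series(beta, index=names),
        ci_lower=pd.Series(lo, index=names),
        ci_upper=pd.Series(hi, index=names),
        bse=bse,
        cov_params=cov,
        r_squared=float(pseudo_r2),
        n_used=len(ya),
        converged=converged,
        diagnostics={
            "n_iterations": n_iter,
            "objective": obj,
            "n_retained": int(mask.sum()),
            "iteration_log": path,
            "bootstrap": None if boot is None else {
                "replicates": boot.replicates, "seed": boot.seed,
                "ci_method": boot.ci_method,
            },
        },
    )
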