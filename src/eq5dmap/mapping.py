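"""Model/Results interface tying the mapping pipeline together.

`UtilityMapping` is built from registry follow-up data (records or a
DataFrame in the documented CSV schema); `fit()` runs one of the three
mapping regressions and returns a `MappingResults` carrying the
coefficients, their 95% intervals, fit statistics, diagnostics, a
`summary()` table, and `predict()`/`validate()` on new data.

Typical use::

    from eq5dmap import UtilityMapping, simulate

    cohort = simulate.generate_cohort(simulate.GeneratorConfig(seed=7))
    est, val = simulate.split_sample(cohort, seed=7)
    res = UtilityMapping(est).fit("tobit")
    print(res.summary())
    report = res.validate(val)
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import validation as _validation
from .coding import (
    COEFFICIENT_NAMES,
    RegistryRecord,
    design_matrix,
    frame_to_records,
)
from .estimators import (
    BootstrapConfig,
    FitResult,
    fit_clad,
    fit_ols_robust,
    fit_tobit,
)
from .model import (
    PUBLISHED_R2,
    CoefficientSet,
    max_attainable,
    predict,
    published_model,
)

logger = logging.getLogger(__name__)

__all__ = ["UtilityMapping", "MappingResults"]


class UtilityMapping:
    """Mapping of registry outcome variables to EQ-5D utility weights.

    Parameters
    ----------
    records : registry records with observed EQ-5D outcomes; records
        lacking an outcome are excluded (complete-case) with a logged count.
    """

    def __init__(self, records: Iterable[RegistryRecord]):
        self.records = list(records)
        self.exog, self.endog, self.n_excluded = design_matrix(self.records)
        if self.n_excluded:
            logger.info(
                "UtilityMapping: %d of %d records excluded for missing outcomes",
                self.n_excluded, len(self.records),
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "UtilityMapping":
        """Build from a DataFrame in the registry CSV schema."""
        return cls(frame_to_records(df))

    @property
    def nobs(self) -> int:
        return len(self.endog)

    def fit(
        self,
        method: str = "ols",
        upper: float = 1.0,
        boot: Optional[BootstrapConfig] = None,
    ) -> "MappingResults":
        """Fit one mapping regression.

        ``method`` is ``"ols"`` (robust HC1 standard errors), ``"tobit"``
        (right-censored Gaussian MLE) or ``"clad"`` (Powell's censored
        least absolute deviation; pass ``boot`` for bootstrap intervals).
        """
        method = method.lower()
        if method == "ols":
            fit = fit_ols_robust(self.exog, self.endog)
        elif method == "tobit":
            fit = fit_tobit(self.exog, self.endog, upper=upper)
        elif method == "clad":
            fit = fit_clad(self.exog, self.endog, upper=upper, boot=boot)
        else:
            raise ValueError(f"unknown method {method!r}; expected ols, tobit or clad")
        return MappingResults(self, fit)

    def vif(self) -> pd.Series:
        """Variance inflation factors of the dummy regressors."""
        return _validation.vif(self.exog)


class MappingResults:
    """Results of one fitted mapping regression.

    Wraps the estimator's :class:`~eq5dmap.estimators.FitResult`; exposes
    the coefficient set for prediction, validation against held-out
    records, and a readable summary table.
    """

    def __init__(self, model: Optional[UtilityMapping], fit: FitResult):
        self.model = model
        self.fit_result = fit

    # -- estimates ---------------------------------------------------------
    @property
    def model_kind(self) -> str:
        return self.fit_result.model_kind

    @property
    def params(self) -> pd.Series:
        return self.fit_result.params

    @property
    def bse(self) -> Optional[pd.Series]:
        return self.fit_result.bse

    @property
    def rsquared(self) -> float:
        """R² for OLS; declared pseudo-R² for Tobit/CLAD."""
        return self.fit_result.r_squared

    @property
    def scale_sigma(self) -> Optional[float]:
        return self.fit_result.scale_sigma

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def conf_int(self) -> pd.DataFrame:
        return self.fit_result.conf_int()

    @property
    def coefficient_set(self) -> CoefficientSet:
        return CoefficientSet.from_fit(self.fit_result, source="fitted")

    def coefficient_correlation(self) -> pd.DataFrame:
        return _validation.coefficient_correlation(self.fit_result)

    @property
    def max_attainable(self) -> float:
        """Largest predictable utility (the all-reference profile)."""
        return max_attainable(self.coefficient_set)

    # -- prediction & validation ------------------------------------------
    def _design_of(self, data) -> tuple[pd.DataFrame, Optional[pd.Series]]:
        if isinstance(data, pd.DataFrame):
            if list(data.columns) == list(COEFFICIENT_NAMES):
                return data, None
            data = frame_to_records(data)
        if isinstance(data, UtilityMapping):
            return data.exog, data.endog
        X, y, _ = design_matrix(list(data))
        return X, y

    def predict(self, data) -> np.ndarray:
        """Predicted EQ-5D weights for records, a schema DataFrame, or a
        ready design matrix (censored at 1 for Tobit/CLAD)."""
        X, _ = self._design_of(data)
        return np.atleast_1d(predict(self.coefficient_set, X))

    def validate(self, data) -> _validation.ValidationReport:
        """Prediction-accuracy report on held-out records with observed outcomes."""
        if isinstance(data, pd.DataFrame):
            data = frame_to_records(data)
        if isinstance(data, UtilityMapping):
            X, y = data.exog, data.endog
        else:
            X, y, n_excl = design_matrix(data)
            if n_excl:
                logger.info("validate: %d record(s) without outcomes excluded", n_excl)
        pred = np.atleast_1d(predict(self.coefficient_set, X))
        return _validation.validate(y.to_numpy(), pred, model_kind=self.model_kind)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Coefficient table with 95% intervals and fit statistics."""
        fr = self.fit_result
        title = {
            "ols": "OLS (HC1 robust standard errors)",
            "tobit": "Tobit, right-censored at 1 (ML)",
            "clad": "CLAD (Powell), censored at 1",
        }[fr.model_kind]
        lines = [
            "EQ-5D utility mapping — " + title,
            f"n = {fr.n_used}    "
            + (f"R² = {fr.r_squared:.3f}" if fr.model_kind == "ols"
               else f"pseudo-R² = {fr.r_squared:.3f}"),
        ]
        if fr.scale_sigma is not None:
            lines[-1] += f"    sigma = {fr.scale_sigma:.3f}"
        if not fr.converged:
            lines.append("WARNING: estimator did not converge; estimates are provisional")
        lines.append(f"{'':<28}{'Coef.':>9}{'[95% CI':>10}{']':>8}")
        for name in fr.params.index:
            lines.append(
                f"{name:<28}{fr.params[name]:>9.3f}"
                f"{fr.ci_lower[name]:>10.3f}{fr.ci_upper[name]:>8.3f}"
            )
        lines.append(f"Maximum attainable prediction: {self.max_attainable:.3f}")
        return "\n".join(lines)

    def to_json(self, **settings) -> str:
        return self.fit_result.to_json(**settings)

    @classmethod
    def from_json(cls, text: str) -> "MappingResults":
        return cls(None, FitResult.from_json(text))

    @classmethod
    def from_published(cls, name: str) -> "MappingResults":
        """Wrap a published coefficient set as a (point-estimate-only) result.

        Interval bounds degenerate to the point estimates; use the
        published article for inference on these models.
        """
        cs = published_model(name)
        params = cs.series
        fit = FitResult(
            model_kind=cs.model_kind,
            params=params,
            ci_lower=params.copy(),
            ci_upper=params.copy(),
            r_squared=PUBLISHED_R2[cs.model_kind],
            n_used=272,
            converged=True,
            diagnostics={"source": cs.source},
        )
        return cls(None, fit)
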