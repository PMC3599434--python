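"""Mapping coefficient sets and censored EQ-5D-weight prediction.

A mapping model is fully described by 12 named coefficients (intercept +
11 dummies) in the frozen column order, plus the model kind, which fixes
the prediction rule: OLS predictions are the raw linear index, while
Tobit and CLAD predictions are censored at the ceiling of 1 — the rule
the estimation applied, so the published Tobit constant of 1.068 predicts
exactly 1.0 for an unimpaired profile.

The three published coefficient sets estimated on the pooled stroke-
registry estimation sample (n = 272) ship as ready-to-use models under
:func:`published_model`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .coding import COEFFICIENT_NAMES, CovariateVector, RegistryRecord, encode
from .estimators import FitResult

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientSet",
    "predict",
    "max_attainable",
    "published_model",
    "PUBLISHED_MODELS",
    "LOWER_TARIFF_BOUND",
]

#: Lowest utility the UK tariff can produce; OLS predictions below it are
#: preserved but logged as a warning.
LOWER_TARIFF_BOUND = -0.594

_PUBLISHED_VALUES = {
    # Published regression coefficients, stored exactly as printed (3 dp),
    # in the frozen coefficient order.
    "ols": (0.902, -0.151, -0.187, -0.191, -0.363, -0.055, -0.155, -0.246,
            -0.074, -0.208, -0.327, -0.132),
    "tobit": (1.068, -0.138, -0.218, -0.230, -0.393, -0.129, -0.233, -0.303,
              -0.137, -0.274, -0.387, -0.141),
    "clad": (1.000, -0.179, -0.247, -0.152, -0.281, -0.121, -0.237, -0.370,
             -0.107, -0.223, -0.471, -0.032),
}

#: Published goodness of fit: R² (OLS) / pseudo-R² (Tobit, CLAD).
PUBLISHED_R2 = {"ols": 0.724, "tobit": 0.657, "clad": 0.486}


@dataclass(frozen=True)
class CoefficientSet:
    """A mapping model: kind, 12 named coefficients, provenance text."""

    model_kind: str
    values: tuple[float, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if self.model_kind not in ("ols", "tobit", "clad"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if len(self.values) != len(COEFFICIENT_NAMES):
            raise ValueError(
                f"expected {len(COEFFICIENT_NAMES)} coefficients, got {len(self.values)}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return COEFFICIENT_NAMES

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.values, index=list(COEFFICIENT_NAMES), dtype=float)

    @classmethod
    def from_mapping(cls, model_kind: str, values: Mapping[str, float], source: str = "") -> "CoefficientSet":
        """Build from a name→value mapping; names must match the frozen order."""
        missing = [n for n in COEFFICIENT_NAMES if n not in values]
        extra = [n for n in values if n not in COEFFICIENT_NAMES]
        if missing or extra:
            raise ValueError(
                f"coefficient names misaligned; missing {missing}, unexpected {extra}"
            )
        return cls(model_kind, tuple(float(values[n]) for n in COEFFICIENT_NAMES), source)

    @classmethod
    def from_fit(cls, fit: FitResult, source: str = "fitted") -> "CoefficientSet":
        return cls.from_mapping(fit.model_kind, dict(fit.params), source)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_kind": self.model_kind,
                "coefficient_names": list(COEFFICIENT_NAMES),
                "coefficients": list(self.values),
                "source": self.source,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CoefficientSet":
        d = json.loads(text)
        values = dict(zip(d["coefficient_names"], d["coefficients"]))
        return cls.from_mapping(d["model_kind"], values, d.get("source", ""))


def _covariate_array(cov) -> np.ndarray:
    if isinstance(cov, CovariateVector):
        return cov.as_array()
    if isinstance(cov, RegistryRecord):
        return encode(cov).as_array()
    arr = np.asarray(cov, dtype=float)
    if arr.shape[-1] != len(COEFFICIENT_NAMES):
        raise ValueError(
            f"covariate row must have {len(COEFFICIENT_NAMES)} entries (intercept first), "
            f"got {arr.shape[-1]}"
        )
    return arr


def predict(coeffs: CoefficientSet, cov) -> Union[float, np.ndarray]:
    """Predicted EQ-5D weight for one covariate profile (or a 2-D batch).

    The linear index is the dot product of coefficients and covariates.
    For Tobit and CLAD models the prediction is censored at 1 — the rule
    applied when those models were estimated; OLS predictions are the raw
    index with neither ceiling nor floor. An OLS prediction below the
    tariff's own minimum (−0.594) is infeasible as an observed utility
    and is logged as a warning, but returned untouched.

    Accepts a :class:`~eq5dmap.coding.CovariateVector`, a
    :class:`~eq5dmap.coding.RegistryRecord`, a length-12 array, or an
    (n, 12) matrix; the covariate order must match the coefficient order.
    """
    if isinstance(cov, pd.DataFrame):
        if list(cov.columns) != list(COEFFICIENT_NAMES):
            raise ValueError("design-matrix columns misaligned with coefficient order")
        cov = cov.to_numpy(dtype=float)
    arr = _covariate_array(cov)
    index = arr @ np.asarray(coeffs.values)
    if coeffs.model_kind in ("tobit", "clad"):
        index = np.minimum(index, 1.0)
    else:
        n_below = int(np.sum(np.atleast_1d(index) < LOWER_TARIFF_BOUND))
        if n_below:
            logger.warning(
                "%d OLS prediction(s) below the tariff minimum %.3f (kept uncensored)",
                n_below, LOWER_TARIFF_BOUND,
            )
    return float(index) if np.ndim(index) == 0 else index


def max_attainable(coeffs: CoefficientSet) -> float:
    """Maximum predictable EQ-5D weight: the all-reference profile, post-censoring.

    With all non-intercept coefficients non-positive (true of every
    published set — each impairment dummy lowers utility) the reference
    profile attains the model maximum; a warning is issued otherwise.
    """
    if any(v > 0 for v in coeffs.values[1:]):
        warnings.warn(
            "some non-intercept coefficients are positive; the all-reference "
            "profile may not attain the maximum", stacklevel=2,
        )
    return float(predict(coeffs, CovariateVector()))


def published_model(name: str) -> CoefficientSet:
    """One of the three published mapping models: ``"ols"``, ``"tobit"``, ``"clad"``.

    Coefficients are stored exactly as printed (three decimals), estimated
    on the pooled stroke-registry estimation sample (n = 272) with EQ-5D
    weights under the UK social tariff as the dependent variable.
    """
    key = str(name).lower()
    if key not in _PUBLISHED_VALUES:
        raise KeyError(
            f"unknown published model {name!r}; expected one of {sorted(_PUBLISHED_VALUES)}"
        )
    return CoefficientSet(
        model_kind=key,
        values=_PUBLISHED_VALUES[key],
        source="published stroke-registry mapping study, estimation set n=272",
    )


PUBLISHED_MODELS: tuple[str, ...] = tuple(_PUBLISHED_VALUES)
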