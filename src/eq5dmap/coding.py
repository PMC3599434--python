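"""Registry follow-up answers and their dummy encoding.

The stroke-register 3-month follow-up questionnaire asks about assistance
needed with toileting and dressing, restricted mobility, perceived general
health and low mood, and records whether a proxy (next of kin or health
professional) answered on the patient's behalf. Each categorical answer is
expanded into dummy variables against the "no disability" reference
category, yielding — with the intercept — the 12-column design row shared
by all three mapping regressions.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .tariff import HealthState, index_uk, parse_state

logger = logging.getLogger(__name__)

__all__ = [
    "MOBILITY_LEVELS",
    "GENERAL_HEALTH_LEVELS",
    "MOOD_LEVELS",
    "COEFFICIENT_NAMES",
    "RegistryRecord",
    "CovariateVector",
    "encode",
    "design_matrix",
    "records_to_frame",
    "frame_to_records",
    "read_registry_csv",
    "write_registry_csv",
]

MOBILITY_LEVELS = ("unrestricted", "indoors_only", "none")
GENERAL_HEALTH_LEVELS = ("very_good", "fairly_good", "fairly_bad", "bad")
MOOD_LEVELS = ("never", "sometimes", "often", "always")

#: Coefficient/column labels in the frozen published-table order.
COEFFICIENT_NAMES = (
    "Constant",
    "Toilet assistance",
    "Dressing assistance",
    "Indoor mobility only",
    "No mobility",
    "General health fairly good",
    "General health fairly bad",
    "General health bad",
    "Moody sometimes",
    "Moody often",
    "Moody always",
    "Proxy response",
)

#: CSV schema column names (lowercase tokens for categorical values).
CSV_COLUMNS = (
    "toilet_assist", "dressing_assist", "mobility", "general_health",
    "mood", "proxy", "eq5d_state", "eq5d_index",
)


class EncodingError(ValueError):
    """An unknown category label for a registry variable."""


def _as_bool(value, name: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        token = value.strip().lower()
        if token in ("yes", "true", "1"):
            return True
        if token in ("no", "false", "0"):
            return False
    raise EncodingError(f"unknown value {value!r} for binary field {name!r}")


@dataclass(frozen=True)
class RegistryRecord:
    """One patient's follow-up answers plus an optional observed EQ-5D outcome.

    ``observed_state`` is the reported EQ-5D-3L profile, ``observed_index``
    the tariff-scored utility. Either (or both, in which case they must
    agree) may be present; records missing both cannot enter estimation.
    Acute-phase characteristics are carried in ``meta`` untouched — they
    play no role in the mapping.
    """

    toilet_assist: bool
    dressing_assist: bool
    mobility: str
    general_health: str
    mood: str
    proxy: bool
    observed_state: Optional[HealthState] = None
    observed_index: Optional[float] = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "toilet_assist", _as_bool(self.toilet_assist, "toilet_assist"))
        object.__setattr__(self, "dressing_assist", _as_bool(self.dressing_assist, "dressing_assist"))
        object.__setattr__(self, "proxy", _as_bool(self.proxy, "proxy"))
        for name, levels in (
            ("mobility", MOBILITY_LEVELS),
            ("general_health", GENERAL_HEALTH_LEVELS),
            ("mood", MOOD_LEVELS),
        ):
            value = getattr(self, name)
            if value not in levels:
                raise EncodingError(
                    f"unknown value {value!r} for field {name!r}; expected one of {levels}"
                )
        if self.observed_state is not None and self.observed_index is not None:
            scored = index_uk(self.observed_state)
            if abs(scored - self.observed_index) > 1e-9:
                raise ValueError(
                    f"observed_index {self.observed_index} disagrees with tariff value "
                    f"{scored} of state {self.observed_state.code}"
                )

    @property
    def outcome(self) -> Optional[float]:
        """Observed utility: the stored index, or the tariff-scored state."""
        if self.observed_index is not None:
            return float(self.observed_index)
        if self.observed_state is not None:
            return float(index_uk(self.observed_state))
        return None


@dataclass(frozen=True)
class CovariateVector:
    """The intercept + 11 dummy regressors of the mapping models.

    Field order is the frozen published-table order; one dummy set per
    non-reference category of each registry variable.
    """

    toilet: int = 0
    dressing: int = 0
    mobility_indoor_only: int = 0
    mobility_none: int = 0
    gh_fairly_good: int = 0
    gh_fairly_bad: int = 0
    gh_bad: int = 0
    mood_sometimes: int = 0
    mood_often: int = 0
    mood_always: int = 0
    proxy: int = 0
    intercept: int = 1

    def __post_init__(self) -> None:
        dummies = self.as_array()
        if self.intercept != 1:
            raise ValueError("intercept is the constant 1")
        if any(v not in (0, 1) for v in dummies):
            raise ValueError("dummies must be 0/1")
        if self.mobility_indoor_only + self.mobility_none > 1:
            raise ValueError("at most one mobility dummy may be set")
        if self.gh_fairly_good + self.gh_fairly_bad + self.gh_bad > 1:
            raise ValueError("at most one general-health dummy may be set")
        if self.mood_sometimes + self.mood_often + self.mood_always > 1:
            raise ValueError("at most one mood dummy may be set")

    def as_array(self) -> np.ndarray:
        """Length-12 0/1 row in published-table order (intercept first)."""
        return np.array(
            [
                self.intercept,
                self.toilet,
                self.dressing,
                self.mobility_indoor_only,
                self.mobility_none,
                self.gh_fairly_good,
                self.gh_fairly_bad,
                self.gh_bad,
                self.mood_sometimes,
                self.mood_often,
                self.mood_always,
                self.proxy,
            ],
            dtype=float,
        )


def encode(record: RegistryRecord) -> CovariateVector:
    """Dummy-encode one registry record against the reference categories.

    The reference profile (no assistance, unrestricted mobility, very good
    health, never low in mood, self-response) encodes to all-zero dummies.
    """
    return CovariateVector(
        toilet=int(record.toilet_assist),
        dressing=int(record.dressing_assist),
        mobility_indoor_only=int(record.mobility == "indoors_only"),
        mobility_none=int(record.mobility == "none"),
        gh_fairly_good=int(record.general_health == "fairly_good"),
        gh_fairly_bad=int(record.general_health == "fairly_bad"),
        gh_bad=int(record.general_health == "bad"),
        mood_sometimes=int(record.mood == "sometimes"),
        mood_often=int(record.mood == "often"),
        mood_always=int(record.mood == "always"),
        proxy=int(record.proxy),
    )


def design_matrix(
    records: Iterable[RegistryRecord],
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Build the estimation design matrix and response vector.

    Records lacking any observed EQ-5D outcome are excluded (complete-case)
    and counted; the response uses the stored index, computed from the
    reported profile when only the profile is present.

    Returns
    -------
    X : DataFrame of 0/1 with intercept column, columns in the frozen order
    y : Series of observed utilities aligned with X
    n_excluded : number of records dropped for a missing outcome
    """
    rows, outcomes = [], []
    n_excluded = 0
    for rec in records:
        outcome = rec.outcome
        if outcome is None:
            n_excluded += 1
            continue
        rows.append(encode(rec).as_array())
        outcomes.append(outcome)
    if n_excluded:
        logger.info("excluded %d record(s) lacking an observed EQ-5D outcome", n_excluded)
    X = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(rows), len(COEFFICIENT_NAMES)),
        columns=list(COEFFICIENT_NAMES),
    )
    y = pd.Series(outcomes, dtype=float, name="eq5d_index")
    return X, y, n_excluded


# ---------------------------------------------------------------------------
# CSV interchange

def records_to_frame(records: Sequence[RegistryRecord]) -> pd.DataFrame:
    """Registry records as a DataFrame in the documented CSV schema."""
    rows = []
    for rec in records:
        rows.append(
            {
                "toilet_assist": "yes" if rec.toilet_assist else "no",
                "dressing_assist": "yes" if rec.dressing_assist else "no",
                "mobility": rec.mobility,
                "general_health": rec.general_health,
                "mood": rec.mood,
                "proxy": "yes" if rec.proxy else "no",
                "eq5d_state": rec.observed_state.code if rec.observed_state else "",
                "eq5d_index": rec.observed_index if rec.observed_index is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[RegistryRecord]:
    """Parse a DataFrame in the registry CSV schema into records.

    Health states are accepted either as 5-digit codes (``eq5d_state``) or
    as five separate level columns (``eq5d_mobility`` … ``eq5d_anxiety``);
    the dialect is auto-detected from the column names.
    """
    level_cols = [f"eq5d_{d}" for d in ("mobility", "selfcare", "activities", "pain", "anxiety")]
    has_levels = all(c in df.columns for c in level_cols)
    records = []
    for _, row in df.iterrows():
        state = None
        if has_levels and not any(pd.isna(row[c]) for c in level_cols):
            state = HealthState(*(int(row[c]) for c in level_cols))
        elif "eq5d_state" in df.columns:
            code = row["eq5d_state"]
            if not (pd.isna(code) or str(code).strip() == ""):
                state = parse_state(str(code).strip())
        index = None
        if "eq5d_index" in df.columns and not (
            pd.isna(row["eq5d_index"]) or str(row["eq5d_index"]).strip() == ""
        ):
            index = float(row["eq5d_index"])
        known = set(CSV_COLUMNS) | set(level_cols)
        meta = {k: row[k] for k in df.columns if k not in known}
        records.append(
            RegistryRecord(
                toilet_assist=row["toilet_assist"],
                dressing_assist=row["dressing_assist"],
                mobility=str(row["mobility"]).strip(),
                general_health=str(row["general_health"]).strip(),
                mood=str(row["mood"]).strip(),
                proxy=row["proxy"],
                observed_state=state,
                observed_index=index,
                meta=meta,
            )
        )
    return records


def read_registry_csv(path) -> list[RegistryRecord]:
    """Read a registry cohort CSV (``#`` lines are treated as comments)."""
    df = pd.read_csv(path, comment="#", dtype={"eq5d_state": str})
    return frame_to_records(df)


def write_registry_csv(records: Sequence[RegistryRecord], path, header_comment: str = "") -> None:
    """Write records in the documented CSV schema, optionally with a
    ``#``-prefixed provenance header."""
    df = records_to_frame(records)
    buf = io.StringIO()
    for line in filter(None, header_comment.splitlines()):
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
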