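"""EQ-5D-3L health states and the UK social tariff.

The EQ-5D-3L describes health on five dimensions — mobility, self-care,
usual activities, pain/discomfort and anxiety/depression — each at three
severity levels (1 = no problems, 2 = some/moderate problems, 3 = extreme
problems), giving 3**5 = 243 distinct profiles. A *tariff* (value set)
converts a profile into a single utility weight anchored at 1 (full health)
and 0 (death); states valued worse than death are negative.

This module implements the UK social tariff (the Dolan time-trade-off
valuation): starting from 1, subtract a constant for any departure from
full health, a per-dimension decrement for each level-2 or level-3
response, and an extra "N3" decrement once if any dimension is at level 3.
Under this tariff the attainable index ranges from −0.594 (state 33333)
to 1.0 (state 11111).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields

__all__ = [
    "DIMENSIONS",
    "HealthState",
    "UKTariff",
    "UK_TARIFF",
    "index_uk",
    "parse_state",
    "enumerate_states",
]

#: Dimension names in instrument order (positions in the 5-digit code).
DIMENSIONS = (
    "mobility",
    "selfcare",
    "activities",
    "pain",
    "anxiety",
)


class InvalidLevelError(ValueError):
    """A dimension level outside the admissible set {1, 2, 3}."""


@dataclass(frozen=True, order=True)
class HealthState:
    """One EQ-5D-3L profile: five ordinal levels, each in {1, 2, 3}.

    Ordering (and therefore sorting) follows the 5-digit code
    lexicographically, e.g. ``11111 < 11112 < ... < 33333``.
    """

    mobility_level: int
    selfcare_level: int
    activities_level: int
    pain_level: int
    anxiety_level: int

    def __post_init__(self) -> None:
        for f, dim in zip(fields(self), DIMENSIONS):
            level = getattr(self, f.name)
            if not isinstance(level, int) or level not in (1, 2, 3):
                raise InvalidLevelError(
                    f"{dim} level must be 1, 2 or 3, got {level!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (
            self.mobility_level,
            self.selfcare_level,
            self.activities_level,
            self.pain_level,
            self.anxiety_level,
        )

    @property
    def code(self) -> str:
        """The 5-digit profile code, e.g. ``"21123"``."""
        return "".join(str(v) for v in self.levels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_state(code: str) -> HealthState:
    """Parse a 5-character digit code (e.g. ``"21123"``) into a HealthState.

    Raises
    ------
    ValueError
        If the code is not five characters, or any character is not a
        digit in 1–3 (the message names the offending dimension).
    """
    code = str(code).strip()
    if len(code) != 5:
        raise ValueError(f"health-state code must have 5 characters, got {code!r}")
    levels = []
    for ch, dim in zip(code, DIMENSIONS):
        if ch not in "123":
            raise ValueError(
                f"invalid level {ch!r} for dimension {dim!r} in code {code!r}"
            )
        levels.append(int(ch))
    return HealthState(*levels)


@dataclass(frozen=True)
class UKTariff:
    """UK social-tariff constants (Dolan valuation).

    ``index = 1 − any_dysfunction_constant·1[state ≠ 11111]
            − Σ per-dimension level decrements − n3_decrement·1[any level 3]``

    All decrements are positive utilities subtracted from full health.
    ``level2_decrements`` / ``level3_decrements`` are ordered like
    :data:`DIMENSIONS`.
    """

    full_health_value: float = 1.0
    any_dysfunction_constant: float = 0.081
    level2_decrements: tuple[float, ...] = (0.069, 0.104, 0.036, 0.123, 0.071)
    level3_decrements: tuple[float, ...] = (0.314, 0.214, 0.094, 0.386, 0.236)
    n3_decrement: float = 0.269

    def __post_init__(self) -> None:
        if len(self.level2_decrements) != 5 or len(self.level3_decrements) != 5:
            raise ValueError("tariff needs one level-2 and one level-3 decrement per dimension")
        decs = (self.any_dysfunction_constant, self.n3_decrement,
                *self.level2_decrements, *self.level3_decrements)
        if any(d <= 0 for d in decs):
            raise ValueError("all tariff decrements must be strictly positive")


#: The default UK social tariff, validated at import time against the
#: published extremes (33333 → −0.594, 11111 → 1.0).
UK_TARIFF = UKTariff()


def index_uk(state: HealthState, tariff: UKTariff = UK_TARIFF) -> float:
    """UK social-tariff index value of an EQ-5D-3L state.

    Returns 1.0 for full health (11111); otherwise subtracts the
    any-dysfunction constant, the level-specific decrement of every
    dimension at level 2 or 3, and the N3 decrement once if any dimension
    is at level 3. Bounded in [−0.594, 1.0] for the default tariff.
    """
    if not isinstance(state, HealthState):
        state = parse_state(state)
    levels = state.levels
    if all(v == 1 for v in levels):
        return tariff.full_health_value
    value = tariff.full_health_value - tariff.any_dysfunction_constant
    for level, d2, d3 in zip(levels, tariff.level2_decrements, tariff.level3_decrements):
        if level == 2:
            value -= d2
        elif level == 3:
            value -= d3
    if any(v == 3 for v in levels):
        value -= tariff.n3_decrement
    return value


def enumerate_states() -> list[HealthState]:
    """All 243 EQ-5D-3L states in lexicographic code order."""
    return [
        HealthState(*levels)
        for levels in itertools.product((1, 2, 3), repeat=5)
    ]


def _validate_default_tariff() -> None:
    # Consistency checksum against the published attainable extremes.
    worst = round(index_uk(parse_state("33333")), 9)
    best = round(index_uk(parse_state("11111")), 9)
    if worst != -0.594 or best != 1.0:
        raise AssertionError(
            f"default UK tariff constants inconsistent with published extremes: "
            f"33333 → {worst}, 11111 → {best}"
        )


_validate_default_tariff()
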