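"""Metachronous ripening-pattern curves and USDA stage storage-period tables.

A ripening pattern composes a cultivar x temperature universal sigmoid curve
with its analytic breaker lag: the curve is meaningful only from the lag
onwards (the model does not describe the green phase), so queries before the
lag return a distinguished ``PRE_BREAKER`` marker instead of the absurd
negative values the raw formula would give there.

Storage periods to the USDA visual stages (breaker, turning, pink, light
red, red) are obtained by inverting the curve at per-stage a* thresholds and
rounding to whole days.  Breaker is a* = 0 by definition; thresholds for the
later stages are configuration.  The shipped defaults beyond breaker are
illustrative a* cut-offs only — USDA defines those stages by percentage of
red surface, not by a chromaticity value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .fitting import UniversalCurve
from .sigmoid import (
    InvalidInputError,
    LagEstimate,
    SigmoidParams,
    UnreachableTargetError,
    equilibrium_a_star,
    evaluate_sigmoid,
    inverse_sigmoid,
    time_lag,
)

__all__ = [
    "PRE_BREAKER",
    "StageThresholds",
    "DEFAULT_STAGE_THRESHOLDS",
    "RipeningPattern",
    "StageTable",
    "UnreachableStageError",
    "build_pattern",
    "days_to_stage",
    "stage_table",
    "round_days",
]

logger = logging.getLogger(__name__)


class _PreBreaker:
    """Sentinel: the queried day precedes breaker; the model is undefined there."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "PRE_BREAKER"


PRE_BREAKER = _PreBreaker()


class UnreachableStageError(ValueError):
    """Stage threshold at or above the curve's equilibrium a*."""


@dataclass(frozen=True)
class StageThresholds:
    """Ordered stage-name -> a* threshold mapping.

    Breaker, if present, must be exactly 0 (its definition); thresholds must
    be strictly increasing in stage order.
    """

    thresholds: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        vals = [v for _, v in self.thresholds]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise InvalidInputError(
                f"stage thresholds must be strictly increasing, got {vals}"
            )
        for name, v in self.thresholds:
            if name.lower() == "breaker" and v != 0.0:
                raise InvalidInputError("breaker threshold must be exactly 0 (a* = 0)")

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "StageThresholds":
        return cls(tuple((str(k), float(v)) for k, v in m.items()))

    def items(self) -> tuple[tuple[str, float], ...]:
        return self.thresholds

    def __len__(self) -> int:
        return len(self.thresholds)


#: Illustrative defaults: breaker is definitional (a* = 0); later cut-offs are
#: plausible a* waypoints, not a published calibration.
DEFAULT_STAGE_THRESHOLDS = StageThresholds.from_mapping(
    {"breaker": 0.0, "turning": 5.0, "pink": 10.0, "light red": 16.0, "red": 22.0}
)


@dataclass(frozen=True)
class RipeningPattern:
    """Universal curve + analytic lag: the full-range ripening prediction."""

    cultivar: str
    temperature_C: float
    params: SigmoidParams
    lag_days: LagEstimate

    def a_star(self, day: float):
        """Predicted a* at ``day``; PRE_BREAKER for days before the lag."""
        if day < self.lag_days.lag_days:
            return PRE_BREAKER
        return evaluate_sigmoid(self.params, day)


@dataclass(frozen=True)
class StageTable:
    """Long-format table of whole-day storage periods to each stage."""

    rows: tuple[tuple[str, float, str, int], ...]  # (cultivar, temp, stage, days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows), columns=["cultivar", "temperature_C", "stage", "days"]
        )

    def to_wide(self) -> pd.DataFrame:
        """Stages as columns (in first-seen order), one row per cultivar x T."""
        df = self.to_frame()
        if df.empty:
            return df
        order = list(dict.fromkeys(df["stage"]))
        wide = df.pivot_table(
            index=["cultivar", "temperature_C"], columns="stage", values="days",
            aggfunc="first", sort=False,
        ).reset_index()
        wide.columns.name = None
        return wide[["cultivar", "temperature_C"] + [s for s in order if s in wide.columns]]


def build_pattern(universal: UniversalCurve) -> RipeningPattern:
    """Compose a universal curve with its analytic breaker lag."""
    lag = time_lag(universal.params)
    return RipeningPattern(
        cultivar=universal.cultivar,
        temperature_C=universal.temperature_C,
        params=universal.params,
        lag_days=lag,
    )


def round_days(day: float, convention: str = "nearest") -> int:
    """Round a continuous storage day to whole days.

    ``nearest`` (half rounds up), ``ceil`` or ``floor``.
    """
    if convention == "nearest":
        return int(math.floor(day + 0.5))
    if convention == "ceil":
        return int(math.ceil(day))
    if convention == "floor":
        return int(math.floor(day))
    raise InvalidInputError(f"unknown rounding convention {convention!r}")


def days_to_stage(
    pattern: RipeningPattern, threshold: float, rounding: str | None = "nearest"
):
    """Storage period until the pattern reaches a* = ``threshold``.

    Threshold 0 (breaker) returns the lag itself.  ``rounding=None`` returns
    the continuous (fractional) day.
    """
    if threshold < 0:
        raise InvalidInputError("stage thresholds are defined for a* >= 0")
    eq = equilibrium_a_star(pattern.params)
    if threshold >= eq:
        raise UnreachableStageError(
            f"a* = {threshold} is at or above the equilibrium a* = {eq:.3g}; "
            "this stage is never reached"
        )
    if threshold == 0.0:
        day = pattern.lag_days.lag_days
    else:
        day = inverse_sigmoid(pattern.params, threshold)
    return day if rounding is None else round_days(day, rounding)


def stage_table(
    universals: Sequence[UniversalCurve],
    thresholds: StageThresholds = DEFAULT_STAGE_THRESHOLDS,
    rounding: str = "nearest",
) -> StageTable:
    """Whole-day storage periods to each stage for each universal curve.

    Stages whose threshold meets or exceeds a curve's equilibrium are left
    out of that curve's rows with a logged warning (e.g. a curve whose
    plateau a* is 24.9 can never reach a threshold of 26).
    """
    rows: list[tuple[str, float, str, int]] = []
    for u in universals:
        pattern = build_pattern(u)
        for stage, thr in thresholds.items():
            try:
                d = days_to_stage(pattern, thr, rounding=rounding)
            except (UnreachableStageError, UnreachableTargetError) as exc:
                logger.warning(
                    "%s at %g degC: stage %r unreachable (%s)",
                    u.cultivar, u.temperature_C, stage, exc,
                )
                continue
            rows.append((u.cultivar, float(u.temperature_C), stage, int(d)))
    return StageTable(tuple(rows))
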