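"""Cubic model of the breaker time lag as a function of storage temperature.

The time lag to breaker shortens sharply as storage temperature rises from
12 to 25 degrees Celsius, then lengthens again at 30 degrees where normal
lycopene accumulation is partially repressed.  A cubic polynomial

    lag(T) = c0 + c1*T + c2*T^2 + c3*T^3        (T in degC, lag in days)

captures this shape per cultivar and lets the lag be interpolated at any
storage temperature inside the experimental span 12-30 degC.  Extrapolation
outside that span is refused by default: ripening above ~30 degC is abnormal
and the model carries no information there.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .fitting import InsufficientDataError
from .sigmoid import InvalidInputError, SigmoidParams, time_lag

__all__ = [
    "LagTemperatureModel",
    "TemperatureRangeError",
    "VALID_RANGE_C",
    "fit_lag_cubic",
    "predict_lag",
    "lag_model_from_params",
]

logger = logging.getLogger(__name__)

VALID_RANGE_C = (12.0, 30.0)


class TemperatureRangeError(ValueError):
    """Temperature outside the model's validated 12-30 degC span."""


@dataclass(frozen=True)
class LagTemperatureModel:
    """Cubic lag(T) for one cultivar, with the fitted (T, lag) knots kept."""

    cultivar: str
    coefficients: tuple[float, float, float, float]  # (c0, c1, c2, c3)
    knots: tuple[tuple[float, float], ...]
    valid_range: tuple[float, float] = VALID_RANGE_C

    def __post_init__(self) -> None:
        if len(self.coefficients) != 4:
            raise InvalidInputError("cubic model needs exactly 4 coefficients")
        if len(self.knots) < 4:
            raise InvalidInputError("cubic model needs at least 4 knots")

    def to_dict(self) -> dict:
        return {
            "cultivar": self.cultivar,
            "coefficients": list(self.coefficients),
            "valid_range": list(self.valid_range),
            "knots": [list(k) for k in self.knots],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LagTemperatureModel":
        return cls(
            cultivar=d["cultivar"],
            coefficients=tuple(float(c) for c in d["coefficients"]),
            knots=tuple((float(t), float(l)) for t, l in d["knots"]),
            valid_range=tuple(float(v) for v in d.get("valid_range", VALID_RANGE_C)),
        )


def fit_lag_cubic(
    points: Sequence[tuple[float, float]], cultivar: str = "unknown"
) -> LagTemperatureModel:
    """Least-squares cubic through (temperature, lag) knots.

    With exactly four distinct temperatures the cubic interpolates them
    exactly; with more it is the least-squares fit (normal equations).
    """
    temps = np.array([t for t, _ in points], dtype=float)
    lags = np.array([l for _, l in points], dtype=float)
    if np.unique(temps).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct temperatures for a cubic, got {np.unique(temps).size}"
        )
    coeffs = npoly.polyfit(temps, lags, 3)
    return LagTemperatureModel(
        cultivar=cultivar,
        coefficients=tuple(float(c) for c in coeffs),
        knots=tuple((float(t), float(l)) for t, l in points),
    )


def predict_lag(
    model: LagTemperatureModel, temperature_C: float, allow_extrapolation: bool = False
) -> float:
    """Lag in days at ``temperature_C`` from the cubic.

    Temperatures outside the valid range raise ``TemperatureRangeError``
    unless ``allow_extrapolation`` is set, in which case a warning is logged.
    """
    lo, hi = model.valid_range
    if not (lo <= temperature_C <= hi):
        if not allow_extrapolation:
            raise TemperatureRangeError(
                f"{temperature_C} degC outside validated range [{lo}, {hi}] degC"
            )
        logger.warning(
            "extrapolating lag model for %s to %g degC (validated range [%g, %g])",
            model.cultivar, temperature_C, lo, hi,
        )
    return float(npoly.polyval(temperature_C, np.asarray(model.coefficients)))


def lag_model_from_params(
    cultivar: str, params_by_temp: Mapping[float, SigmoidParams]
) -> LagTemperatureModel:
    """Build the cubic from closed-form lags of cultivar-average curves.

    The knots are the analytic breaker lags of each temperature's average
    parameter set, matching how the per-cultivar lag profiles are derived.
    """
    knots = sorted(
        (float(t), time_lag(p).lag_days) for t, p in params_by_temp.items()
    )
    return fit_lag_cubic(knots, cultivar=cultivar)
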