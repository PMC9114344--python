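"""Closed-form tools for the modified sigmoid ripening curve.

Postharvest red-colour development of a mature-green tomato, measured as the
CIE a* colour coordinate (negative = green, positive = red), follows a
logistic-type curve of the storage period ``x`` (days since harvest)::

    a*(x) = alpha / (1 + exp(beta * x)) + gamma

with amplitude ``alpha > 0`` (a* units), rate ``beta < 0`` (1/day) and offset
``gamma < 0`` (a* units).  The curve rises from the lower asymptote ``gamma``
to the upper asymptote (equilibrium, fully-ripe colour) ``alpha + gamma``,
which for normally ripening fruit sits near a* = 24-26.

The breaker stage — first visible colour break — is defined as the moment the
curve crosses a* = 0.  Inverting the model at zero gives the *time lag*::

    lag = ln[(alpha + gamma) / (-gamma)] / beta

the number of days from harvest until red colour development begins.  This
module provides exact evaluation, inversion, lag and equilibrium computation,
plus JSON (de)serialisation and the packaged cultivar-average parameter sets
for the three reference cultivars (Miracle, Rei-getsu, Momotaro York) stored
at 12, 15, 20, 25 and 30 degrees Celsius.

Only the red phase (a* > 0, "P2") is described by the model; the green lag
phase before breaker is outside its domain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SigmoidParams",
    "LagEstimate",
    "InvalidInputError",
    "UnreachableTargetError",
    "NoBreakerCrossingError",
    "DegenerateCurveError",
    "evaluate_sigmoid",
    "inverse_sigmoid",
    "time_lag",
    "equilibrium_a_star",
    "load_default_parameters",
]

# exp argument clip; exp(±700) is the edge of double range.  Physical storage
# periods (0-60 d) with |beta| <= 5 stay far inside, so clipping never alters
# results in the modelled range.
_EXP_CLIP = 700.0


class InvalidInputError(ValueError):
    """A parameter or argument is non-finite or otherwise malformed."""


class UnreachableTargetError(ValueError):
    """Requested a* value lies outside the curve's open range (gamma, alpha+gamma)."""


class NoBreakerCrossingError(ValueError):
    """The curve never crosses a* = 0 (alpha + gamma <= 0 or gamma >= 0)."""


class DegenerateCurveError(ValueError):
    """beta does not describe a rising ripening curve (beta >= 0 or beta == 0)."""


@dataclass(frozen=True)
class SigmoidParams:
    """Parameter triple (alpha, beta, gamma) of one ripening curve.

    alpha : amplitude, a* units, > 0 for a valid curve
    beta  : rate, 1/day, < 0 for a valid (rising) curve
    gamma : offset, a* units, < 0 for a valid curve

    A valid curve additionally has a positive equilibrium
    ``alpha + gamma > 0`` so that breaker (a* = 0) is reached.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")

    @property
    def equilibrium(self) -> float:
        """Upper asymptote alpha + gamma (fully-ripe a*)."""
        return self.alpha + self.gamma

    def is_valid_ripening_curve(self) -> bool:
        """True when (alpha > 0, beta < 0, gamma < 0, alpha + gamma > 0)."""
        return self.alpha > 0 and self.beta < 0 and self.gamma < 0 and self.equilibrium > 0

    def to_dict(self, cultivar: str | None = None, temperature_C: float | None = None) -> dict:
        d: dict = {}
        if cultivar is not None:
            d["cultivar"] = cultivar
        if temperature_C is not None:
            d["temperature_C"] = temperature_C
        d.update(alpha=self.alpha, beta=self.beta, gamma=self.gamma)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SigmoidParams":
        return cls(float(d["alpha"]), float(d["beta"]), float(d["gamma"]))


@dataclass(frozen=True)
class LagEstimate:
    """Time lag to breaker: days from harvest until predicted a* reaches 0."""

    lag_days: float

    def __float__(self) -> float:
        return self.lag_days


def _check_day(day) -> np.ndarray:
    arr = np.asarray(day, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"day must be finite, got {day!r}")
    return arr


def evaluate_sigmoid(params: SigmoidParams, day):
    """Predicted CIE a* at storage day(s) ``day``.

    Accepts a scalar or array of days; returns the same shape.  Strictly
    increasing in ``day`` for a valid ripening curve (alpha > 0, beta < 0).
    """
    arr = _check_day(day)
    z = np.clip(params.beta * arr, -_EXP_CLIP, _EXP_CLIP)
    out = params.alpha / (1.0 + np.exp(z)) + params.gamma
    return float(out) if np.isscalar(day) or arr.ndim == 0 else out


def inverse_sigmoid(params: SigmoidParams, target: float) -> float:
    """Storage day at which the curve reaches a* = ``target``.

    ``target`` must lie strictly between the asymptotes
    (gamma, alpha + gamma); values at or beyond them are never attained.
    """
    if not math.isfinite(target):
        raise InvalidInputError(f"target must be finite, got {target!r}")
    if params.beta == 0:
        raise DegenerateCurveError("beta = 0: constant curve cannot be inverted")
    lo, hi = params.gamma, params.alpha + params.gamma
    if not (lo < target < hi):
        raise UnreachableTargetError(
            f"a* = {target} is outside the attainable open interval ({lo}, {hi})"
        )
    return math.log(params.alpha / (target - params.gamma) - 1.0) / params.beta


def time_lag(params: SigmoidParams) -> LagEstimate:
    """Time lag to breaker, ``ln[(alpha+gamma)/(-gamma)] / beta`` days.

    Requires a curve that actually crosses zero: alpha + gamma > 0 and
    gamma < 0, with beta < 0 for a rising curve.
    """
    if params.beta == 0:
        raise DegenerateCurveError("beta = 0: constant curve has no breaker crossing")
    if params.equilibrium <= 0 or params.gamma >= 0:
        raise NoBreakerCrossingError(
            "curve never crosses a* = 0 (needs alpha + gamma > 0 and gamma < 0); "
            f"got alpha+gamma = {params.equilibrium}, gamma = {params.gamma}"
        )
    return LagEstimate(math.log(params.equilibrium / (-params.gamma)) / params.beta)


def equilibrium_a_star(params: SigmoidParams) -> float:
    """Fully-ripe plateau a*: the upper asymptote alpha + gamma (beta < 0)."""
    if params.beta >= 0:
        raise DegenerateCurveError(
            f"beta must be negative for alpha+gamma to be the upper asymptote, got {params.beta}"
        )
    return params.equilibrium


# ---------------------------------------------------------------------------
# Packaged cultivar-average parameters
# ---------------------------------------------------------------------------

def load_default_parameters() -> dict[str, dict[float, SigmoidParams]]:
    """Packaged cultivar-average parameters, cultivar -> {temperature_C -> params}.

    These are the average fitted (alpha, beta, gamma) for five biological
    replicates of each of the three reference cultivars at each of the five
    storage temperatures (fifteen parameter sets in total).
    """
    text = resources.files("metaripe").joinpath("data/default_parameters.json").read_text()
    out: dict[str, dict[float, SigmoidParams]] = {}
    for row in json.loads(text):
        out.setdefault(row["cultivar"], {})[float(row["temperature_C"])] = SigmoidParams.from_dict(row)
    return out


def params_to_json(entries: Iterable[tuple[str, float, SigmoidParams]]) -> str:
    """Serialise (cultivar, temperature, params) triples to the JSON dialect."""
    return json.dumps(
        [p.to_dict(cultivar=c, temperature_C=t) for c, t, p in entries], indent=1
    )


def params_from_json(text: str) -> list[tuple[str, float, SigmoidParams]]:
    """Parse the JSON parameter dialect back into (cultivar, T, params) triples."""
    return [
        (row["cultivar"], float(row["temperature_C"]), SigmoidParams.from_dict(row))
        for row in json.loads(text)
    ]
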