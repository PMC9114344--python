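"""Seeded generator of per-fruit CIE a* ripening trajectories.

Emulates the statistical structure of a storage trial with mature-green
tomatoes: each fruit starts green (a* drawn in the -6 to -5 band), sits in a
green lag phase whose length depends on storage temperature and varies
between individual fruits (the metachronous property), then rises along the
sigmoid curve to a plateau near a* 24-26.  Colour is sampled daily and
carries additive Gaussian measurement noise.

Forward model for fruit *i* at day *d*:

    latent(d) = max( green(d),  sigmoid(d - s_i) )
    observed(d) = latent(d) + N(0, noise_sd)

where ``s_i ~ N(0, jitter_sd)`` is the fruit's onset shift and ``green`` is
a monotone exponential relaxation from the drawn initial a* toward 0 scaled
to sit near a* = -1 one day before the shifted breaker.  The max() hands the
trajectory from the green baseline to the sigmoid exactly where the sigmoid
overtakes it, so the latent series is monotone and equals the sigmoid for
every day at or after the (shifted) lag.  The green branch is illustrative
plumbing for testing the partition logic — it is never fitted.

Determinism: every stochastic draw for fruit *i* comes from a generator
seeded by ``(master_seed, i)``, so a cohort is bit-reproducible and fruit
*i*'s trajectory does not change when the cohort is subset or enlarged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .fitting import ColorPoint, ColorTrajectory
from .sigmoid import (
    InvalidInputError,
    SigmoidParams,
    evaluate_sigmoid,
    load_default_parameters,
    time_lag,
)

__all__ = [
    "CohortProfile",
    "simulate_trajectory",
    "simulate_cohort",
    "default_profiles",
]


@dataclass(frozen=True)
class CohortProfile:
    """Study-design description of one cultivar's simulated storage trial.

    Defaults mirror the reference trial: initial a* in [-6, -5] at harvest
    (truncated normal, mean -5.5, sd 0.3), measurement noise sd 0.5 a*
    units, inter-fruit onset jitter sd 1 day, daily sampling, and a duration
    of 1.5 x the true lag + 20 days so the plateau is well covered.
    """

    cultivar: str
    params_by_temp: Mapping[float, SigmoidParams]
    initial_a_mean: float = -5.5
    initial_a_sd: float = 0.3
    initial_a_range: tuple[float, float] = (-6.0, -5.0)
    noise_sd: float = 0.5
    lag_jitter_sd: float = 1.0
    sampling_interval_days: float = 1.0
    duration_days: float | None = None  # None -> 1.5 * true lag + 20

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.lag_jitter_sd < 0:
            raise InvalidInputError("noise and jitter standard deviations must be >= 0")
        if self.sampling_interval_days <= 0:
            raise InvalidInputError("sampling interval must be positive")
        if self.duration_days is not None and self.duration_days < 0:
            raise InvalidInputError("duration must be non-negative")
        for t, p in self.params_by_temp.items():
            if not p.is_valid_ripening_curve():
                raise InvalidInputError(
                    f"invalid ripening-curve parameters for {self.cultivar} at {t} degC"
                )


def _draw_initial_a(rng: np.random.Generator, profile: CohortProfile) -> float:
    lo, hi = profile.initial_a_range
    for _ in range(1000):
        v = rng.normal(profile.initial_a_mean, profile.initial_a_sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(profile.initial_a_mean, lo, hi))  # pragma: no cover


def _green_baseline(days: np.ndarray, a0: float, shifted_lag: float) -> np.ndarray:
    # exponential relaxation a0 * exp(-k d) toward 0, calibrated to pass
    # through a* = -1 one day before the shifted breaker
    t1 = max(shifted_lag - 1.0, 0.5)
    k = math.log(-a0) / t1  # a0 < -1 always (initial band is [-6, -5])
    return a0 * np.exp(-k * days)


def simulate_trajectory(
    true_params: SigmoidParams,
    profile: CohortProfile,
    lag_shift: float = 0.0,
    seed: int | tuple[int, ...] = 0,
    fruit_id: str = "sim-0",
    temperature_C: float = float("nan"),
) -> ColorTrajectory:
    """Simulate one fruit's daily a* trajectory.

    ``lag_shift`` displaces the whole sigmoid horizontally by that many days
    (the fruit's individual onset); the shared curve shape is unchanged.
    Identical (params, profile, lag_shift, seed) give identical output.
    """
    rng = np.random.default_rng(seed)
    base_lag = time_lag(true_params).lag_days
    duration = (
        profile.duration_days
        if profile.duration_days is not None
        else 1.5 * base_lag + 20.0
    )
    if duration < 0:
        raise InvalidInputError("duration must be non-negative")
    n = int(math.floor(duration / profile.sampling_interval_days + 1e-9)) + 1
    days = np.arange(n) * profile.sampling_interval_days

    a0 = _draw_initial_a(rng, profile)
    green = _green_baseline(days, a0, base_lag + lag_shift)
    red = evaluate_sigmoid(true_params, days - lag_shift)
    latent = np.maximum(green, red)
    observed = latent + rng.normal(0.0, profile.noise_sd, size=n) if profile.noise_sd > 0 else latent

    pts = tuple(ColorPoint(float(d), float(a)) for d, a in zip(days, observed))
    return ColorTrajectory(
        fruit_id=fruit_id,
        cultivar=profile.cultivar,
        temperature_C=float(temperature_C),
        points=pts,
    )


def simulate_cohort(
    profile: CohortProfile,
    temperature_C: float,
    n_fruits: int = 5,
    seed: int = 0,
) -> list[ColorTrajectory]:
    """Simulate a cohort of fruits at one storage temperature.

    Each fruit's onset shift is drawn N(0, jitter sd) from a generator
    seeded by (master seed, fruit index), so trajectories are stable under
    cohort subsetting.
    """
    if n_fruits < 1:
        raise InvalidInputError("n_fruits must be >= 1")
    key = next(
        (t for t in profile.params_by_temp if abs(t - temperature_C) <= 0.01), None
    )
    if key is None:
        raise InvalidInputError(
            f"no parameters for {profile.cultivar} at {temperature_C} degC; "
            f"available: {sorted(profile.params_by_temp)}"
        )
    params = profile.params_by_temp[key]
    out = []
    for i in range(n_fruits):
        shift_rng = np.random.default_rng((seed, i, 1))
        shift = float(shift_rng.normal(0.0, profile.lag_jitter_sd))
        out.append(
            simulate_trajectory(
                params,
                profile,
                lag_shift=shift,
                seed=(seed, i, 2),
                fruit_id=f"{profile.cultivar}-{key:g}C-{i:02d}",
                temperature_C=key,
            )
        )
    return out


def default_profiles() -> dict[str, CohortProfile]:
    """Default cohort profiles for the three reference cultivars.

    True parameters are the packaged cultivar-average sets for all fifteen
    cultivar x temperature combinations.
    """
    return {
        cultivar: CohortProfile(cultivar=cultivar, params_by_temp=by_temp)
        for cultivar, by_temp in load_default_parameters().items()
    }
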