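"""Per-fruit curve fitting of CIE a* trajectories and cohort averaging.

Each fruit contributes a daily time series of CIE a* during storage.  The
series is split at a* = 0 into the green phase P1 (a* < 0) and the red
development phase P2 (a* > 0, exact zeros included); the sigmoid model is
fitted to P2 only by bounded trust-region nonlinear least squares.  Because
the data observe only the upper limb of the logistic, alpha and gamma are
strongly anti-correlated; individual parameter values are therefore not
identified, but the fitted curve and the derived time lag are, and those are
what downstream prediction uses.

Per (cultivar, temperature) group the fitted parameters are averaged
arithmetically into a "universal" curve describing that group's typical
ripening trajectory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .sigmoid import (
    InvalidInputError,
    SigmoidParams,
    evaluate_sigmoid,
)

__all__ = [
    "ColorPoint",
    "ColorTrajectory",
    "GoodnessOfFit",
    "FitResult",
    "UniversalCurve",
    "FitOptions",
    "CohortFit",
    "InsufficientDataError",
    "DegenerateDataError",
    "partition_trajectory",
    "fit_sigmoid",
    "goodness_of_fit",
    "average_parameters",
    "fit_cohort",
    "read_trajectories",
    "write_trajectories",
    "fits_to_frame",
]

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["fruit_id", "cultivar", "temperature_C", "day", "a_star"]

# temperatures within this tolerance (deg C) are treated as the same group
TEMPERATURE_TOL = 0.01


class InsufficientDataError(ValueError):
    """Too few P2 points (or too few distinct days) to fit three parameters."""


class DegenerateDataError(ValueError):
    """Observations carry no usable signal (all identical)."""


@dataclass(frozen=True)
class ColorPoint:
    """One colour observation: storage day since harvest and CIE a* value."""

    day: float
    a_star: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.day) and self.day >= 0):
            raise InvalidInputError(f"day must be finite and >= 0, got {self.day!r}")
        if not math.isfinite(self.a_star):
            raise InvalidInputError(f"a_star must be finite, got {self.a_star!r}")


@dataclass(frozen=True)
class ColorTrajectory:
    """One fruit's ordered colour time series with cultivar/temperature metadata."""

    fruit_id: str
    cultivar: str
    temperature_C: float
    points: tuple[ColorPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise InvalidInputError("trajectory must contain at least one point")
        days = [p.day for p in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InvalidInputError(f"days must be strictly increasing for {self.fruit_id}")

    @property
    def days(self) -> np.ndarray:
        return np.array([p.day for p in self.points])

    @property
    def a_star(self) -> np.ndarray:
        return np.array([p.a_star for p in self.points])


@dataclass(frozen=True)
class GoodnessOfFit:
    """R^2, RMSE and %RMSE of a fit over the P2 observations.

    %RMSE is RMSE divided by the root of the raw sum of squared observed a*
    values, times 100 (note: the denominator is the root *sum*, not the root
    mean, so the measure shrinks with n for fixed signal level).
    """

    r2: float
    rmse: float
    pct_rmse: float
    n_points: int


@dataclass(frozen=True)
class FitResult:
    """One fruit's fitted curve plus diagnostics."""

    fruit_id: str
    params: SigmoidParams
    gof: GoodnessOfFit
    converged: bool
    n_iterations: int
    cultivar: str | None = None
    temperature_C: float | None = None


@dataclass(frozen=True)
class UniversalCurve:
    """Arithmetic mean of per-fruit parameters for one cultivar x temperature."""

    cultivar: str
    temperature_C: float
    params: SigmoidParams
    n_fruits: int

    def __post_init__(self) -> None:
        if self.n_fruits < 1:
            raise InvalidInputError("a universal curve must average at least one fit")


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings for the bounded trust-region least-squares fit."""

    beta_init: float = -0.2
    beta_grid: tuple[float, ...] = (-0.05, -0.2, -0.6)
    ftol: float = 1e-10
    xtol: float = 1e-12
    max_nfev: int = 10_000
    # bounds keep the fit inside the valid-ripening-curve region without
    # constraining realistic parameter magnitudes
    alpha_max: float = 1e5
    beta_min: float = -5.0
    gamma_min: float = -1e5


@dataclass
class CohortFit:
    """Batch result: per-fruit fits, per-group universal curves, skip log."""

    fits: list[FitResult] = field(default_factory=list)
    universal_curves: list[UniversalCurve] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)


def partition_trajectory(
    traj: ColorTrajectory,
) -> tuple[list[ColorPoint], list[ColorPoint]]:
    """Split a trajectory at a* = 0 into (P1 green, P2 red) point lists.

    Exact zeros go to P2: a* = 0 defines breaker, the start of the red
    development phase the model describes.  Order is preserved.
    """
    p1 = [p for p in traj.points if p.a_star < 0]
    p2 = [p for p in traj.points if p.a_star >= 0]
    return p1, p2


def goodness_of_fit(observed: Sequence[float], predicted: Sequence[float]) -> GoodnessOfFit:
    """Score predictions: R^2 about the observed mean, RMSE, and %RMSE."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InvalidInputError(
            f"observed and predicted must be equal-length 1-D, got {obs.shape} vs {pred.shape}"
        )
    if obs.size < 2:
        raise InvalidInputError("need at least 2 observations to score a fit")
    sse = float(np.sum((obs - pred) ** 2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        raise DegenerateDataError("observed values have zero variance; R^2 undefined")
    rmse = math.sqrt(sse / obs.size)
    pct = rmse / math.sqrt(float(np.sum(obs**2))) * 100.0
    return GoodnessOfFit(r2=1.0 - sse / sstot, rmse=rmse, pct_rmse=pct, n_points=obs.size)


def _default_init(days: np.ndarray, a: np.ndarray, beta0: float) -> np.ndarray:
    # geometry of the observed upper limb: the plateau is near max(a*), and
    # fitted offsets sit far below it, so seed gamma below the data and alpha
    # to put alpha + gamma at the observed maximum
    amax = float(a.max())
    gamma0 = -2.0 * max(amax, 1.0)
    alpha0 = max(amax, 1.0) - gamma0
    return np.array([alpha0, beta0, gamma0])


def fit_sigmoid(
    p2_points: Sequence[ColorPoint],
    init: SigmoidParams | None = None,
    options: FitOptions | None = None,
    fruit_id: str = "",
) -> FitResult:
    """Fit the sigmoid curve to one fruit's P2 points by least squares.

    Needs at least 4 points (3 parameters + 1 residual df) on at least 3
    distinct days.  On optimiser failure a multi-start over a small grid of
    initial rates is attempted; persistent failure yields a result with
    ``converged=False`` rather than an exception.
    """
    opts = options or FitOptions()
    if len(p2_points) < 4:
        raise InsufficientDataError(
            f"need >= 4 red-phase points to fit 3 parameters, got {len(p2_points)}"
        )
    days = np.array([p.day for p in p2_points], dtype=float)
    a = np.array([p.a_star for p in p2_points], dtype=float)
    if np.unique(days).size < 3:
        raise InsufficientDataError("need >= 3 distinct days")
    if np.ptp(a) == 0.0:
        raise DegenerateDataError("all a* values identical; curve not identifiable")

    lb = np.array([1e-8, opts.beta_min, opts.gamma_min])
    ub = np.array([opts.alpha_max, -1e-8, -1e-8])

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = SigmoidParams(*theta)
        return evaluate_sigmoid(p, days) - a

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(np.array([init.alpha, init.beta, init.gamma]))
    starts.append(_default_init(days, a, opts.beta_init))
    for b0 in opts.beta_grid:
        if b0 != opts.beta_init:
            starts.append(_default_init(days, a, b0))

    best = None
    total_nfev = 0
    for theta0 in starts:
        theta0 = np.clip(theta0, lb, ub)
        res = least_squares(
            residuals,
            theta0,
            bounds=(lb, ub),
            method="trf",
            ftol=opts.ftol,
            xtol=opts.xtol,
            max_nfev=opts.max_nfev,
        )
        total_nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
        # multi-start is a fallback: stop at the first converged valid curve
        if res.success and SigmoidParams(*res.x).is_valid_ripening_curve():
            best = res if res.cost <= best.cost else best
            break

    assert best is not None
    params = SigmoidParams(*best.x)
    pred = evaluate_sigmoid(params, days)
    gof = goodness_of_fit(a, pred)
    converged = bool(best.success) and params.is_valid_ripening_curve()
    # objective never increases relative to the first default start
    return FitResult(
        fruit_id=fruit_id,
        params=params,
        gof=gof,
        converged=converged,
        n_iterations=int(total_nfev),
    )


def average_parameters(
    fits: Sequence[FitResult],
    require_converged: bool = True,
    cultivar: str | None = None,
    temperature_C: float | None = None,
) -> UniversalCurve:
    """Average per-fruit parameters component-wise into a universal curve.

    All fits must belong to one cultivar and one storage temperature.  With
    ``require_converged`` (default) non-converged fits are excluded before
    averaging.
    """
    if len(fits) == 0:
        raise InvalidInputError("cannot average an empty collection of fits")
    cultivars = {f.cultivar for f in fits if f.cultivar is not None}
    temps = {f.temperature_C for f in fits if f.temperature_C is not None}
    if cultivar is not None:
        cultivars.add(cultivar)
    if temperature_C is not None:
        temps.add(float(temperature_C))
    if len(cultivars) > 1:
        raise InvalidInputError(f"mixed cultivars in one average: {sorted(cultivars)}")
    if len(temps) > 1 and max(temps) - min(temps) > TEMPERATURE_TOL:
        raise InvalidInputError(f"mixed temperatures in one average: {sorted(temps)}")
    use = [f for f in fits if f.converged] if require_converged else list(fits)
    if not use:
        raise InvalidInputError("no converged fits to average (require_converged=True)")
    mean = SigmoidParams(
        alpha=float(np.mean([f.params.alpha for f in use])),
        beta=float(np.mean([f.params.beta for f in use])),
        gamma=float(np.mean([f.params.gamma for f in use])),
    )
    return UniversalCurve(
        cultivar=next(iter(cultivars), "unknown"),
        temperature_C=next(iter(temps), float("nan")),
        params=mean,
        n_fruits=len(use),
    )


def fit_cohort(
    trajectories: Iterable[ColorTrajectory],
    options: FitOptions | None = None,
    require_converged: bool = True,
) -> CohortFit:
    """Partition, fit and average a whole cohort of trajectories.

    Fruits with fewer than 4 red-phase points are skipped with a reason;
    each (cultivar, temperature) group with at least one usable fit yields a
    universal curve.
    """
    out = CohortFit()
    groups: dict[tuple[str, float], list[FitResult]] = {}
    for traj in trajectories:
        _, p2 = partition_trajectory(traj)
        try:
            fit = fit_sigmoid(p2, options=options, fruit_id=traj.fruit_id)
        except (InsufficientDataError, DegenerateDataError) as exc:
            out.skipped.append((traj.fruit_id, str(exc)))
            logger.info("skipping %s: %s", traj.fruit_id, exc)
            continue
        fit = replace(fit, cultivar=traj.cultivar, temperature_C=traj.temperature_C)
        logger.info(
            "fitted %s (%s, %g degC): converged=%s R2=%.4f",
            traj.fruit_id, traj.cultivar, traj.temperature_C, fit.converged, fit.gof.r2,
        )
        out.fits.append(fit)
        key = next(
            (k for k in groups if k[0] == traj.cultivar
             and abs(k[1] - traj.temperature_C) <= TEMPERATURE_TOL),
            (traj.cultivar, float(traj.temperature_C)),
        )
        groups.setdefault(key, []).append(fit)
    for (cultivar, temp), fits in groups.items():
        try:
            out.universal_curves.append(
                average_parameters(fits, require_converged=require_converged)
            )
        except InvalidInputError as exc:
            logger.warning("no universal curve for (%s, %g degC): %s", cultivar, temp, exc)
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_trajectories(path) -> list[ColorTrajectory]:
    """Read long-format trajectory CSV (fruit_id,cultivar,temperature_C,day,a_star).

    Lines starting with ``#`` (provenance headers) are ignored.  Rows are
    grouped by fruit and sorted by day.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"trajectory CSV missing column(s) {missing} in {path}")
    if len(df) == 0:
        raise InvalidInputError(f"no data rows in {path}")
    bad = df[~np.isfinite(df["day"]) | ~np.isfinite(df["a_star"])]
    if len(bad):
        # +2: 1-based line numbers plus header line
        raise InvalidInputError(
            f"non-numeric day/a_star near line {int(bad.index[0]) + 2} of {path}"
        )
    trajectories = []
    for (fid, cultivar, temp), g in df.groupby(
        ["fruit_id", "cultivar", "temperature_C"], sort=False
    ):
        g = g.sort_values("day")
        pts = tuple(ColorPoint(float(d), float(a)) for d, a in zip(g["day"], g["a_star"]))
        trajectories.append(
            ColorTrajectory(str(fid), str(cultivar), float(temp), pts)
        )
    return trajectories


def write_trajectories(trajectories: Iterable[ColorTrajectory], path, header: str | None = None) -> None:
    """Write trajectories in the long CSV dialect, optional ``#`` provenance header."""
    rows = [
        {"fruit_id": t.fruit_id, "cultivar": t.cultivar, "temperature_C": t.temperature_C,
         "day": p.day, "a_star": p.a_star}
        for t in trajectories
        for p in t.points
    ]
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def fits_to_frame(fits: Sequence[FitResult], universals: Sequence[UniversalCurve] = ()) -> pd.DataFrame:
    """Tabulate per-fruit fits and universal curves with a shared schema."""
    rows = []
    for f in fits:
        rows.append({
            "fruit_id": f.fruit_id, "cultivar": f.cultivar, "temperature_C": f.temperature_C,
            "alpha": f.params.alpha, "beta": f.params.beta, "gamma": f.params.gamma,
            "r2": f.gof.r2, "rmse": f.gof.rmse, "pct_rmse": f.gof.pct_rmse,
            "n_points": f.gof.n_points, "converged": f.converged,
        })
    for u in universals:
        rows.append({
            "fruit_id": None, "cultivar": u.cultivar, "temperature_C": u.temperature_C,
            "alpha": u.params.alpha, "beta": u.params.beta, "gamma": u.params.gamma,
            "r2": None, "rmse": None, "pct_rmse": None,
            "n_points": u.n_fruits, "converged": True,
        })
    return pd.DataFrame(rows)
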