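"""Trajectory partitioning, per-fruit least-squares fits, cohort averaging."""

import math

import numpy as np
import pytest

from metaripe import (
    ColorPoint,
    ColorTrajectory,
    DegenerateDataError,
    FitResult,
    InsufficientDataError,
    InvalidInputError,
    SigmoidParams,
    average_parameters,
    evaluate_sigmoid,
    fit_cohort,
    fit_sigmoid,
    goodness_of_fit,
    partition_trajectory,
    read_trajectories,
    simulate_cohort,
    time_lag,
    write_trajectories,
)


def _traj(days, a_stars, fruit_id="f1", cultivar="Miracle", temp=15.0):
    return ColorTrajectory(
        fruit_id, cultivar, temp,
        tuple(ColorPoint(float(d), float(a)) for d, a in zip(days, a_stars)),
    )


class TestPartition:
    def test_sign_split(self):
        t = _traj(range(6), [-5, -3, -1, 2, 10, 20])
        p1, p2 = partition_trajectory(t)
        assert [p.a_star for p in p1] == [-5, -3, -1]
        assert [p.a_star for p in p2] == [2, 10, 20]

    def test_all_green_gives_empty_red_part(self):
        p1, p2 = partition_trajectory(_traj(range(3), [-5, -4, -3]))
        assert p2 == [] and len(p1) == 3

    def test_exact_zero_is_red_phase(self):
        # a* = 0 is the breaker definition and opens the fitted phase
        _, p2 = partition_trajectory(_traj(range(3), [-1, 0.0, 2]))
        assert [p.a_star for p in p2] == [0.0, 2]

    def test_trajectory_validation(self):
        with pytest.raises(InvalidInputError):
            _traj([0, 1, 1], [0, 1, 2])  # non-increasing days
        with pytest.raises(InvalidInputError):
            _traj([], [])


class TestFitSigmoid:
    def test_noiseless_round_trip(self, default_params):
        true = default_params["Miracle"][15.0]
        days = np.arange(8.0, 22.0)
        pts = [ColorPoint(d, evaluate_sigmoid(true, d)) for d in days]
        fit = fit_sigmoid(pts)
        assert fit.converged
        pred = evaluate_sigmoid(fit.params, days)
        truth = evaluate_sigmoid(true, days)
        assert np.max(np.abs(pred - truth)) < 1e-4
        assert time_lag(fit.params).lag_days == pytest.approx(
            time_lag(true).lag_days, abs=1e-3
        )
        # noiseless self-fit is essentially perfect
        assert fit.gof.r2 > 1 - 1e-10

    def test_noisy_cohorts_recover_lag(self, profiles):
        # scaled-down Monte Carlo of the recovery property (full version in
        # the acceptance suite)
        prof = profiles["Rei-getsu"]
        true_lag = time_lag(prof.params_by_temp[20.0]).lag_days
        errs = []
        for rep in range(15):
            cohort = simulate_cohort(prof, 20.0, n_fruits=5, seed=500 + rep)
            res = fit_cohort(cohort)
            fitted = time_lag(res.universal_curves[0].params).lag_days
            errs.append(abs(fitted - true_lag))
        assert float(np.median(errs)) < 0.5

    def test_objective_not_worse_than_initial_guess(self, default_params):
        true = default_params["Momotaro York"][20.0]
        rng = np.random.default_rng(7)
        days = np.arange(12.0, 35.0)
        pts = [
            ColorPoint(d, evaluate_sigmoid(true, d) + rng.normal(0, 0.5)) for d in days
        ]
        fit = fit_sigmoid(pts)
        a = np.array([p.a_star for p in pts])
        # initial guess per the default heuristic
        amax = a.max()
        init = SigmoidParams(3 * amax, -0.2, -2 * amax)
        sse_init = float(np.sum((evaluate_sigmoid(init, days) - a) ** 2))
        sse_fit = float(np.sum((evaluate_sigmoid(fit.params, days) - a) ** 2))
        assert sse_fit <= sse_init

    def test_too_few_points(self):
        pts = [ColorPoint(d, v) for d, v in [(0, 1.0), (1, 2.0), (2, 3.0)]]
        with pytest.raises(InsufficientDataError):
            fit_sigmoid(pts)

    def test_constant_data_degenerate(self):
        pts = [ColorPoint(float(d), 5.0) for d in range(5)]
        with pytest.raises(DegenerateDataError):
            fit_sigmoid(pts)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        g = goodness_of_fit([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert (g.r2, g.rmse, g.pct_rmse) == (1.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        # SSE = 3, SStot = 200, sqrt(sum obs^2) = sqrt(1400)
        g = goodness_of_fit([10.0, 20.0, 30.0], [11.0, 19.0, 31.0])
        assert g.rmse == pytest.approx(1.0, rel=1e-12)
        assert g.r2 == pytest.approx(0.985, rel=1e-12)
        assert g.pct_rmse == pytest.approx(100.0 / math.sqrt(1400.0), rel=1e-12)

    def test_pct_rmse_independent_arithmetic(self):
        obs = [3.0, 7.0, 12.0, 18.0]
        pred = [2.5, 8.0, 11.0, 19.0]
        g = goodness_of_fit(obs, pred)
        sse = sum((o - p) ** 2 for o, p in zip(obs, pred))
        rmse = math.sqrt(sse / len(obs))
        assert g.pct_rmse == pytest.approx(
            rmse / math.sqrt(sum(o * o for o in obs)) * 100.0, rel=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            goodness_of_fit([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            goodness_of_fit([1.0, 2.0], [1.0])


class TestAverageParameters:
    def _fit(self, alpha, beta, gamma, cultivar="Miracle", temp=12.0):
        g = goodness_of_fit([1.0, 2.0], [1.0, 2.0])
        return FitResult("f", SigmoidParams(alpha, beta, gamma), g, True, 1,
                         cultivar=cultivar, temperature_C=temp)

    def test_idempotent_on_identical_fits(self):
        fits = [self._fit(100.0, -0.2, -90.0)] * 5
        u = average_parameters(fits)
        assert (u.params.alpha, u.params.beta, u.params.gamma) == (100.0, -0.2, -90.0)
        assert u.n_fruits == 5

    def test_component_wise_mean(self):
        u = average_parameters([self._fit(100, -0.2, -90), self._fit(200, -0.4, -180)])
        assert (u.params.alpha, u.params.beta, u.params.gamma) == pytest.approx(
            (150.0, -0.3, -135.0)
        )

    def test_empty_and_mixed_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            average_parameters([])
        with pytest.raises(InvalidInputError):
            average_parameters(
                [self._fit(100, -0.2, -90), self._fit(100, -0.2, -90, cultivar="Rei-getsu")]
            )
        with pytest.raises(InvalidInputError):
            average_parameters(
                [self._fit(100, -0.2, -90), self._fit(100, -0.2, -90, temp=20.0)]
            )


class TestFitCohort:
    def test_simulated_cohort_recovery(self, profiles):
        prof = profiles["Miracle"]
        cohort = simulate_cohort(prof, 12.0, n_fruits=5, seed=42)
        res = fit_cohort(cohort)
        assert len(res.fits) == 5
        assert len(res.universal_curves) == 1
        true_lag = time_lag(prof.params_by_temp[12.0]).lag_days
        got = time_lag(res.universal_curves[0].params).lag_days
        assert abs(got - true_lag) < 1.0
        assert all(f.gof.r2 >= 0.90 for f in res.fits)

    def test_never_crossing_fruit_is_skipped(self, profiles):
        prof = profiles["Miracle"]
        cohort = simulate_cohort(prof, 15.0, n_fruits=3, seed=1)
        green = _traj(range(10), [-5 + 0.1 * d for d in range(10)], fruit_id="stuck")
        res = fit_cohort(cohort + [green])
        assert len(res.fits) == 3
        assert res.skipped and res.skipped[0][0] == "stuck"

    def test_empty_input(self):
        res = fit_cohort([])
        assert res.fits == [] and res.universal_curves == [] and res.skipped == []


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path, profiles):
        cohort = simulate_cohort(profiles["Rei-getsu"], 25.0, n_fruits=2, seed=9)
        path = tmp_path / "traj.csv"
        write_trajectories(cohort, path, header="provenance line")
        assert path.read_text().startswith("# provenance line")
        back = read_trajectories(path)
        assert [t.fruit_id for t in back] == [t.fruit_id for t in cohort]
        np.testing.assert_allclose(back[0].a_star, cohort[0].a_star, rtol=1e-12)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("fruit_id,cultivar,temperature_C,day\nf,M,12,0\n")
        with pytest.raises(InvalidInputError, match="a_star"):
            read_trajectories(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("fruit_id,cultivar,temperature_C,day,a_star\n")
        with pytest.raises(InvalidInputError):
            read_trajectories(p)
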