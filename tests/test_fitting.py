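"""Calibration machinery: objective, F* profiling, annealing, workflow steps."""

import warnings

import numpy as np
import pandas as pd
import pytest

from vinephen.evaluation import FitMetrics
from vinephen.fitting import (
    AnnealSchedule,
    ConfigError,
    FitResult,
    ParamSpace,
    VarietyYear,
    anneal,
    assemble_dataset,
    build_validation_matrix,
    calibrate_per_variety,
    compare_start_windows,
    estimate_fstar,
    external_validate,
    fit_global,
    make_params,
    objective,
    select_model,
)
from vinephen.synthetic import ClimateScenario, VarietyTruth, generate_observations
from vinephen.thermal import GDDParams

from conftest import constant_series, profiled_grid_loss


def _constant_dataset(n_years, mean=10.0, observed_day=8, variety="V"):
    return [
        VarietyYear(variety, 2000 + i, constant_series(mean, n_days=120), observed_day)
        for i in range(n_years)
    ]


def _synthetic_dataset(seed=5, truth=None, n_years=12, stage="09", variety="V"):
    truth = truth or GDDParams(t0=49, tb=5.0, fstar=228.5)
    vt = VarietyTruth(
        variety,
        budburst=truth,
        flowering=GDDParams(t0=52, tb=6.0, fstar=626.0),
        noise_sd_days=0.0,
        visit_interval_budburst=0,
        visit_interval_flowering=0,
    )
    obs, met = generate_observations(ClimateScenario(seed=seed), [vt], list(range(2008, 2008 + n_years)))
    return assemble_dataset(obs, met, stage)


class TestObjective:
    def test_perfect_params_score_zero(self):
        ds = _constant_dataset(12, observed_day=10)
        assert objective(GDDParams(t0=1, tb=5.0, fstar=50.0), ds) == 0.0

    def test_two_days_late_over_twelve_years(self):
        # constant 5 degree-days/day: F*=50 crosses on day 10; observed day 8
        ds = _constant_dataset(12, observed_day=8)
        assert objective(GDDParams(t0=1, tb=5.0, fstar=50.0), ds) == 48.0

    def test_unreachable_threshold_penalised_finitely(self):
        ds = _constant_dataset(12, observed_day=8)
        loss = objective(GDDParams(t0=1, tb=40.0, fstar=50.0), ds)
        assert np.isfinite(loss)
        # penalty (end-of-series prediction) dwarfs any realistic SSres
        assert loss == 12 * (120 - 8) ** 2


class TestEstimateFstar:
    def test_constant_rate_exact(self):
        ds = _constant_dataset(1, observed_day=10)
        assert estimate_fstar(GDDParams(t0=1, tb=5.0, fstar=1.0), ds) == 50.0

    def test_mean_of_two_years(self):
        ds = [
            VarietyYear("V", 2000, constant_series(9.0, n_days=120), 10),  # 4/day -> 40
            VarietyYear("V", 2001, constant_series(11.0, n_days=120), 10),  # 6/day -> 60
        ]
        assert estimate_fstar(GDDParams(t0=1, tb=5.0, fstar=1.0), ds) == 50.0

    def test_exact_crossing_recovers_generating_threshold(self):
        # crossing is exact on constant data, so the mean rule inverts it
        ds = _constant_dataset(3, observed_day=10)
        params = GDDParams(t0=1, tb=5.0, fstar=50.0)
        assert estimate_fstar(params, ds) == 50.0

    def test_zero_forcing_year_excluded_with_warning(self):
        ds = [
            VarietyYear("V", 2000, constant_series(10.0, n_days=120), 10),
            VarietyYear("V", 2001, constant_series(3.0, n_days=120), 10),
        ]
        with pytest.warns(UserWarning, match="2001"):
            f = estimate_fstar(GDDParams(t0=1, tb=5.0, fstar=1.0), ds)
        assert f == 50.0

    def test_all_years_zero_forcing_errors(self):
        ds = _constant_dataset(2, mean=3.0)
        with pytest.raises(ValueError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimate_fstar(GDDParams(t0=1, tb=5.0, fstar=1.0), ds)


class TestAnneal:
    def test_same_seed_reproduces_fit(self, quick_schedule):
        ds = _synthetic_dataset(n_years=6)
        space = ParamSpace.default("gdd", t0=(1, 150))
        a = anneal(space, ds, seed=4, schedule=quick_schedule)
        b = anneal(space, ds, seed=4, schedule=quick_schedule)
        assert a.params == b.params
        assert a.loss == b.loss
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_empty_bounds_rejected(self):
        with pytest.raises(ConfigError):
            ParamSpace.default("gdd", tb=(10.0, 5.0))

    def test_noiseless_fit_is_exact(self, quick_schedule):
        ds = _synthetic_dataset(n_years=8)
        fit = anneal(ParamSpace.default("gdd", t0=(1, 150)), ds, seed=0, schedule=quick_schedule)
        assert fit.loss == 0.0
        assert fit.metrics.eff == 1.0
        assert (fit.predictions["predicted"] == fit.predictions["observed"]).all()

    def test_matches_exhaustive_grid_on_discrete_problem(self, quick_schedule):
        """Annealing on an integer (t0, Tb) grid finds the grid optimum."""
        ds = _synthetic_dataset(
            truth=GDDParams(t0=49, tb=5.0, fstar=228.5), n_years=12
        )
        space = ParamSpace(
            "gdd", bounds={"t0": (40, 60), "tb": (0.0, 10.0)}, steps={"tb": 1.0}
        )
        grid_best = min(
            profiled_grid_loss(ds, t0, float(tb))
            for t0 in range(40, 61)
            for tb in range(0, 11)
        )
        for seed in (0, 1, 2):
            fit = anneal(space, ds, seed=seed, schedule=quick_schedule)
            assert fit.loss <= grid_best + 1e-9

    def test_range_columns_cover_best_fit(self, quick_schedule):
        ds = _synthetic_dataset(n_years=8)
        fit = anneal(ParamSpace.default("gdd", t0=(1, 150)), ds, seed=1, schedule=quick_schedule)
        for name in ("t0", "tb"):
            mx, mn = fit.param_ranges[name]
            assert mn <= getattr(fit.params, name) <= mx


class TestStartWindows:
    def test_spring_truth_keeps_january_window(self, quick_schedule):
        ds = _synthetic_dataset(seed=5)
        cmp = compare_start_windows(ds, "gdd", seed=2, schedule=quick_schedule)
        assert cmp.selected == "jan"
        assert cmp.jan.metrics.eff >= cmp.sep.metrics.eff

    def test_autumn_truth_needs_september_window(self, quick_schedule):
        truth = GDDParams(t0=-50, tb=0.0, fstar=1350.0)
        ds = _synthetic_dataset(seed=5, truth=truth)
        cmp = compare_start_windows(ds, "gdd", seed=2, schedule=quick_schedule)
        assert cmp.selected == "sep"
        assert cmp.sep.metrics.eff > cmp.jan.metrics.eff


class TestCalibrationAndValidation:
    def test_identical_data_identical_fits(self, quick_schedule):
        base = _synthetic_dataset(n_years=6)
        doubled = base + [
            VarietyYear("W", vy.year, vy.series, vy.observed_day) for vy in base
        ]
        fits = calibrate_per_variety(doubled, "gdd", seed=3, schedule=quick_schedule)
        assert fits["V"].params == fits["W"].params

    def test_short_variety_skipped_with_warning(self, quick_schedule):
        ds = _synthetic_dataset(n_years=6)
        ds.append(VarietyYear("Stub", 2008, ds[0].series, ds[0].observed_day))
        with pytest.warns(UserWarning, match="Stub"):
            fits = calibrate_per_variety(ds, "gdd", seed=0, schedule=quick_schedule)
        assert set(fits) == {"V"}

    def test_self_validation_reproduces_estimation_metrics(self, quick_schedule):
        ds = _synthetic_dataset(n_years=8)
        fit = anneal(ParamSpace.default("gdd", t0=(1, 150)), ds, seed=1, schedule=quick_schedule)
        again = external_validate(fit, ds)
        assert again == fit.metrics

    def test_parameter_mismatch_degrades_transfer(self, quick_schedule):
        donor_ds = _synthetic_dataset(seed=9, truth=GDDParams(t0=49, tb=5.0, fstar=228.5))
        fit = anneal(ParamSpace.default("gdd", t0=(1, 150)), donor_ds, seed=1, schedule=quick_schedule)
        matched = external_validate(fit, donor_ds)
        mismatched_ds = _synthetic_dataset(
            seed=9, truth=GDDParams(t0=49, tb=10.0, fstar=228.5), variety="M"
        )
        mismatched = external_validate(fit, mismatched_ds)
        assert mismatched.eff < matched.eff

    def test_validation_matrix_diagonal_is_estimation(self, quick_schedule):
        ds = _synthetic_dataset(n_years=6) + _synthetic_dataset(
            seed=8, n_years=6, variety="W", truth=GDDParams(t0=60, tb=7.0, fstar=150.0)
        )
        fits = calibrate_per_variety(ds, "gdd", seed=2, schedule=quick_schedule)
        groups = {v: [vy for vy in ds if vy.variety == v] for v in fits}
        vm = build_validation_matrix(fits, groups)
        for v in fits:
            assert vm.eff.loc[v, v] == fits[v].metrics.eff
            assert vm.rmse.loc[v, v] == fits[v].metrics.rmse

    def test_global_fit_pools_all_years(self, quick_schedule):
        ds = _synthetic_dataset(n_years=3) + _synthetic_dataset(
            seed=8, n_years=3, variety="W"
        )
        fit = fit_global(ds, "gdd", seed=0, schedule=quick_schedule)
        assert fit.metrics.n == 6


class TestModelSelection:
    @staticmethod
    def _result(model_type, eff):
        params = {
            "gdd": {"t0": 50, "tb": 5.0},
            "triangular": {"t0": 50, "tmin_c": 5.0, "topt": 20.0, "tmax_c": 35.0},
            "uniforc": {"t0": 50, "d": -1.0, "e": 12.0},
        }[model_type]
        return FitResult(
            model_type=model_type,
            params=make_params(model_type, params, 100.0),
            loss=0.0,
            metrics=FitMetrics(eff=eff, rmse=1.0, mad=1.0, n=12),
            predictions=pd.DataFrame(),
            param_ranges={},
            metric_ranges={},
            n_starts=1,
            seed=0,
        )

    def test_near_tie_prefers_gdd(self):
        results = {
            "gdd": self._result("gdd", 0.950),
            "triangular": self._result("triangular", 0.955),
        }
        assert select_model(results) == "gdd"

    def test_clear_winner_overrides_simplicity(self):
        results = {
            "gdd": self._result("gdd", 0.80),
            "triangular": self._result("triangular", 0.95),
        }
        assert select_model(results) == "triangular"
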