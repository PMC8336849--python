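"""Diagnostics and exhaustive-search fitting tests."""

import itertools

import numpy as np
import pytest

import ageflux as af
from ageflux.fitting import FitSpec, _observation_steps


class TestRSquared:
    def test_perfect_fit(self):
        assert af.r_squared([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert af.r_squared(obs, np.full(3, obs.mean())) == 0.0

    def test_hand_computed_example(self):
        assert af.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_total_variation_is_an_error(self):
        with pytest.raises(af.ValidationError):
            af.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestMdape:
    def test_identical_series(self):
        assert af.mdape([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_median(self):
        assert af.mdape([10.0, 20.0], [9.0, 24.0]) == pytest.approx(0.15)

    def test_single_point(self):
        assert af.mdape([4.0], [5.0]) == pytest.approx(0.25)

    def test_near_zero_observations_dropped(self):
        # baseline-subtracted data can have zeros; they leave the median
        assert af.mdape([0.0, 10.0], [3.0, 9.0]) == pytest.approx(0.1)

    def test_all_zero_is_an_error(self):
        with pytest.raises(af.ValidationError):
            af.mdape([0.0, 0.0], [1.0, 1.0])


class TestObservedSeries:
    def test_validation(self):
        with pytest.raises(af.ValidationError):
            af.ObservedSeries([0, 1, 2], [1, 2, 3])  # too short
        with pytest.raises(af.ValidationError):
            af.ObservedSeries([0, 1, 1, 2], [1, 2, 3, 4])  # duplicate
        with pytest.raises(af.ValidationError):
            af.ObservedSeries([0, 1, 2, 4], [1, 2, 3, 4])  # non-uniform
        with pytest.raises(af.ValidationError):
            af.ObservedSeries([0, 1, 2, 3], [1, 2, 3, 4],
                              organism_class="fungus")

    def test_lifespan_lower_bound_units(self):
        s_min = af.ObservedSeries([0, 5, 10, 15], [1, 2, 3, 4],
                                  organism_class="yeast")
        assert s_min.lifespan_lower_bound() == 10.0
        s_h = af.ObservedSeries([0, 1, 2, 3], [1, 2, 3, 4],
                                organism_class="mammalian", time_unit="h")
        assert s_h.lifespan_lower_bound() == 2.0


def _series(pulse=1.4, survival=(0.9, 0.9, 0.5, 0.0), demand=2.0,
            horizon=14, **kw):
    spec = af.SyntheticSeriesSpec(survival=np.array(survival),
                                  pulse_level=pulse, demand=demand,
                                  horizon=horizon, step_length=5.0, **kw)
    return af.generate_series(spec)


SMALL_SPEC = dict(
    lifespans=[10.0, 20.0, 30.0],
    survival_grids=[[0.3, 0.5, 0.9]] * 3,
    pulse_grid=[0.7, 1.4, 2.1],
    demand_grid=[1.0, 2.0, 3.0],
    initial_patterns=np.zeros((1, 5)),
    refine_pulse=False,
)


class TestFitExhaustive:
    def test_noise_free_on_grid_series_recovered_exactly(self):
        series, truth = _series()
        fit = af.fit_exhaustive(series, FitSpec(**SMALL_SPEC))
        assert fit.sse == 0.0
        assert fit.lifespan == 20.0
        assert fit.pulse_level == 1.4
        assert fit.survival_rates == (0.9, 0.9, 0.5)
        assert fit.demand == 2.0
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.mdape == pytest.approx(0.0, abs=1e-12)

    def test_fit_satisfies_conservation(self):
        series, _ = _series()
        fit = af.fit_exhaustive(series, FitSpec(**SMALL_SPEC))
        assert fit.accumulated_transcription - fit.accumulated_degradation \
            == pytest.approx(fit.trajectory.tb[-1] - fit.trajectory.tb[0])

    def test_deterministic_given_spec(self):
        series, _ = _series(noise="additive", sigma=0.1, seed=3)
        a = af.fit_exhaustive(series, FitSpec(**SMALL_SPEC)).to_dict()
        b = af.fit_exhaustive(series, FitSpec(**SMALL_SPEC)).to_dict()
        assert a == b

    def test_matches_brute_force_enumeration(self):
        """SSE of the returned fit is minimal over the whole grid, checked
        against direct enumeration through the reference simulator."""
        series, _ = _series(noise="additive", sigma=0.2, seed=9)
        spec = FitSpec(**{**SMALL_SPEC, "lifespans": [20.0]})
        fit = af.fit_exhaustive(series, spec)
        best = np.inf
        for d0, d1, d2, pulse, demand in itertools.product(
                *([[0.3, 0.5, 0.9]] * 3), [0.7, 1.4, 2.1], [1.0, 2.0, 3.0]):
            profile = af.AgeProfile([d0, d1, d2, 0.0], np.ones(5))
            traj = af.simulate(profile, af.PulsePolicy(pulse),
                               af.ConstantDemand(demand), 14)
            sse = float(np.sum((traj.tb - series.levels) ** 2))
            best = min(best, sse)
        assert fit.sse == pytest.approx(best)

    def test_ties_prefer_smaller_demand(self):
        # demands 2.0 and 2.2 induce identical gating on this series
        # (no activity value ever falls between them): exact SSE tie,
        # resolved deterministically toward the smaller demand
        series, _ = _series()
        spec = FitSpec(**{**SMALL_SPEC, "demand_grid": [2.0, 2.2]})
        fit = af.fit_exhaustive(series, spec)
        assert fit.sse == 0.0
        assert fit.demand == 2.0

    def test_budget_exceeded_reports_cardinality(self):
        series, _ = _series()
        spec = FitSpec(**{**SMALL_SPEC, "max_evaluations": 10})
        with pytest.raises(af.BudgetExceededError) as err:
            af.fit_exhaustive(series, spec)
        assert err.value.cardinality == 3 * 27 * 3 * 3

    def test_organism_bound_filters_lifespans(self):
        series, _ = _series()
        series.organism_class = "mammalian"  # bound 120 min > all candidates
        with pytest.raises(af.ValidationError):
            af.fit_exhaustive(series, FitSpec(**SMALL_SPEC))

    def test_nearest_step_alignment_warns(self):
        series, _ = _series()
        spec = FitSpec(**{**SMALL_SPEC, "lifespans": [15.0]})
        with pytest.warns(UserWarning, match="nearest-step"):
            af.fit_exhaustive(series, spec)

    def test_pulse_refinement_reaches_off_coarse_grid_values(self):
        series, truth = _series(pulse=1.4)
        spec = FitSpec(lifespans=[20.0], survival_grids=[[0.9], [0.9], [0.5]],
                       demand_grid=[2.0], initial_patterns=np.zeros((1, 5)),
                       refine_pulse=True)
        fit = af.fit_exhaustive(series, spec)  # data-driven coarse grid
        assert fit.pulse_level == pytest.approx(1.4, abs=1e-9)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)


class TestWindowedDemand:
    def test_constant_demand_series_gives_equal_windows(self):
        series, _ = _series(horizon=15)
        spec = FitSpec(scenario="windowed_demand", window_size=4,
                       lifespans=[20.0], survival_grids=[[0.9], [0.9], [0.5]],
                       pulse_grid=[1.4], demand_grid=[1.0, 2.0, 3.0])
        fit = af.estimate_demand_windowed(series, spec)
        assert fit.demand == [2.0] * len(fit.demand)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_rotating_demand_recovered_in_order(self):
        rot = af.RotationDemand([2.0, 3.0], [8, 8])
        series, _ = _series(demand=rot, horizon=31)
        spec = FitSpec(scenario="windowed_demand", window_size=8,
                       lifespans=[20.0], survival_grids=[[0.9], [0.9], [0.5]],
                       pulse_grid=[1.4], demand_grid=[2.0, 3.0])
        fit = af.estimate_demand_windowed(series, spec)
        assert fit.demand == [2.0, 3.0, 2.0, 3.0]
        assert fit.window_bounds == [(0, 8), (8, 16), (16, 24), (24, 32)]

    def test_series_shorter_than_window_is_an_error(self):
        series, _ = _series(horizon=5)
        spec = FitSpec(scenario="windowed_demand", window_size=8)
        with pytest.raises(af.ValidationError):
            af.estimate_demand_windowed(series, spec)


class TestMetabolicReport:
    def test_net_rates_are_accumulated_over_duration(self):
        series, _ = _series()
        fit = af.fit_exhaustive(series, FitSpec(**SMALL_SPEC))
        report = af.metabolic_report(fit, duration=70.0)
        assert report["net_transcription_rate"] == pytest.approx(
            fit.accumulated_transcription / 70.0)
        assert report["net_degradation_rate"] == pytest.approx(
            fit.accumulated_degradation / 70.0)

    def test_rate_arithmetic(self):
        # 20.4 units over 70 minutes -> 0.2914.. units/min
        series, _ = _series()
        fit = af.fit_exhaustive(series, FitSpec(**SMALL_SPEC))
        fit.accumulated_transcription = 20.4
        report = af.metabolic_report(fit, duration=70.0)
        assert report["net_transcription_rate"] == pytest.approx(0.29142857)


class TestAlignment:
    def test_integer_divisor_spacing(self):
        # sampling every 5 with a 2.5-unit step: observations at even steps
        series = af.ObservedSeries([0, 5, 10, 15], [0, 1, 2, 3])
        steps = _observation_steps(series, 2.5)
        np.testing.assert_array_equal(steps, [0, 2, 4, 6])
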