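import itertools
import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdmap.ingest import ObservationMinute, TemperatureSample
from herdmap.temporal import (
    classify_intensity,
    extract_bouts,
    fit_activity_grazing_line,
    grazing_proportions,
    hourly_profile,
    midpoint_threshold,
    series_compare_temperature,
    spearman_rho,
    threshold_from_fit,
    GrazingPeriod,
    LinearFit,
)
from tests.conftest import T0, sample

UTC = timezone.utc


def minutes(animal, start, labels, observer="o1"):
    return [
        ObservationMinute(animal, start + timedelta(minutes=i), lab, observer)
        for i, lab in enumerate(labels)
    ]


class TestGrazingProportions:
    def test_fully_grazing_interval(self):
        obs = minutes("c1", T0, ["grazing"] * 30)
        periods = grazing_proportions(obs, [sample("c1", 0, 4000)])
        assert len(periods) == 1
        assert periods[0].proportion_grazing == 1.0
        assert periods[0].minutes_observed == 30

    def test_half_grazing(self):
        obs = minutes("c1", T0, ["grazing"] * 15 + ["non_grazing"] * 15)
        periods = grazing_proportions(obs, [sample("c1", 0, 2500)])
        assert periods[0].proportion_grazing == 0.5

    def test_partial_coverage_excluded(self):
        obs = minutes("c1", T0, ["grazing"] * 20)
        periods = grazing_proportions(obs, [sample("c1", 0, 4000)],
                                      min_coverage=1.0)
        assert periods == []

    def test_partial_coverage_included_when_relaxed(self):
        obs = minutes("c1", T0, ["grazing"] * 20)
        periods = grazing_proportions(obs, [sample("c1", 0, 4000)],
                                      min_coverage=0.5)
        assert periods[0].proportion_grazing == 1.0
        assert periods[0].minutes_observed == 20

    def test_proportions_in_unit_interval_and_classes_partition(
            self, small_herd, small_observations):
        periods = grazing_proportions(small_observations, small_herd.activity)
        assert periods
        assert all(0.0 <= p.proportion_grazing <= 1.0 for p in periods)
        excl_g = sum(p.proportion_grazing == 1.0 for p in periods)
        excl_n = sum(p.proportion_grazing == 0.0 for p in periods)
        mixed = sum(0.0 < p.proportion_grazing < 1.0 for p in periods)
        assert excl_g + excl_n + mixed == len(periods)


class TestLinearFit:
    def _periods(self, xy):
        return [GrazingPeriod("c1", T0, x, int(y), 30) for x, y in xy]

    def test_exact_line_r2_one(self):
        fit = fit_activity_grazing_line(
            self._periods([(0.0, 600), (0.5, 2400), (1.0, 4200)]))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3600.0)

    def test_flat_pattern_r2_zero(self):
        fit = fit_activity_grazing_line(
            self._periods([(0.0, 0), (0.5, 1), (1.0, 0)]))
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_permutation_invariance(self):
        pts = [(0.1, 700), (0.4, 2100), (0.9, 3900), (0.6, 2600)]
        fits = [fit_activity_grazing_line(self._periods(perm))
                for perm in itertools.permutations(pts)]
        assert all(f.slope == pytest.approx(fits[0].slope) for f in fits)
        assert all(f.r_squared == pytest.approx(fits[0].r_squared) for f in fits)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.random(12)
            y = 3000 * x + 500 + rng.normal(0, 200, 12)
            periods = self._periods(zip(x, y))
            fit = fit_activity_grazing_line(periods)
            y_used = np.array([p.activity_index for p in periods], dtype=float)
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y_used)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10 * max(1, abs(beta[0])))
            assert fit.slope == pytest.approx(beta[1], abs=1e-10 * max(1, abs(beta[1])))
            resid = y_used - X @ beta
            r2 = 1 - resid @ resid / ((y_used - y_used.mean()) @ (y_used - y_used.mean()))
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            fit_activity_grazing_line(
                self._periods([(0.5, 100), (0.5, 200), (0.5, 300)]))


class TestThresholds:
    def test_linear_evaluation(self):
        fit = LinearFit(slope=4000.0, intercept=600.0, r_squared=0.9,
                        p_value=0.001, n=50)
        assert threshold_from_fit(fit, 0.5) == pytest.approx(2600.0)
        assert threshold_from_fit(fit, 0.0) == pytest.approx(600.0)
        assert threshold_from_fit(fit, 1.0) == pytest.approx(4600.0)

    def test_zero_slope_errors(self):
        fit = LinearFit(0.0, 600.0, 0.0, 1.0, 10)
        with pytest.raises(ValueError):
            threshold_from_fit(fit, 0.5)

    def test_midpoint_rounds_half_away_from_zero(self):
        assert midpoint_threshold(1848, 2617) == 2233
        assert midpoint_threshold(0, 0) == 0
        assert midpoint_threshold(2500, 2500) == 2500
        assert midpoint_threshold(1, 2) == 2  # 1.5 rounds up


class TestClassifyIntensity:
    def test_boundary_is_high(self):
        labels, _ = classify_intensity([sample("c1", 0, 2499),
                                        sample("c1", 1800, 2500)])
        assert labels == ["low", "high"]

    def test_all_zero_day(self):
        samples = [sample("c1", 1800 * k, 0) for k in range(48)]
        _, daily = classify_intensity(samples)
        assert daily.iloc[0]["low"] == 48
        assert daily.iloc[0]["high"] == 0

    def test_daily_counts_partition_samples(self, small_herd):
        _, daily = classify_intensity(small_herd.activity)
        assert (daily["low"] + daily["high"]).sum() == len(small_herd.activity)


class TestHourlyProfile:
    def test_single_hour(self):
        samples = [sample("c1", 10 * 3600 + 900 * k, 4000) for k in range(4)]
        prof = hourly_profile(samples)
        row10 = prof[(prof["hour"] == 10)].iloc[0]
        assert row10["mean_index"] == pytest.approx(4000.0)
        assert row10["n"] == 4
        assert prof[prof["hour"] == 3].iloc[0]["n"] == 0

    def test_combined_pools_animals(self):
        samples = ([sample("c1", 10 * 3600, 1000)]
                   + [sample("c2", 10 * 3600, 3000)])
        prof = hourly_profile(samples, group="combined")
        assert prof[prof["hour"] == 10].iloc[0]["mean_index"] == pytest.approx(2000.0)

    def test_per_animal_preserves_constants(self):
        samples = ([sample("c1", 10 * 3600, 1000)]
                   + [sample("c2", 10 * 3600, 3000)])
        prof = hourly_profile(samples, group="per_animal").set_index(["animal_id", "hour"])
        assert prof.loc[("c1", 10), "mean_index"] == pytest.approx(1000.0)
        assert prof.loc[("c2", 10), "mean_index"] == pytest.approx(3000.0)

    def test_timezone_offset_shifts_bins(self):
        samples = [sample("c1", 23 * 3600, 500)]
        prof = hourly_profile(samples, tz_offset_hours=1.0)
        assert prof[prof["hour"] == 0].iloc[0]["n"] == 1


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0]
        rho, _ = spearman_rho(x, [2.0, 5.0, 9.0, 11.0])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(x, [11.0, 9.0, 5.0, 2.0])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_matches_scipy_on_all_small_permutations(self):
        for n in (3, 4, 5):
            x = list(range(n))
            for perm in itertools.permutations(range(n)):
                y = list(perm)
                if len(set(y)) < 2:
                    continue
                rho, p = spearman_rho(x, y)
                ref_rho, _ = stats.spearmanr(x, y)
                assert rho == pytest.approx(ref_rho, abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [10.0, 20.0, 20.0, 30.0]
        rho, _ = spearman_rho(x, y)
        ref_rho, _ = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)

    def test_p_value_matches_t_distribution(self):
        rng = np.random.default_rng(8)
        x = rng.random(40)
        y = x + rng.normal(0, 0.5, 40)
        rho, p = spearman_rho(x, y)
        t = rho * math.sqrt(38 / (1 - rho ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 38), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBouts:
    def test_run_length_hand_example(self):
        obs = minutes("c1", T0, ["grazing"] * 3 + ["non_grazing"] * 2 + ["grazing"])
        bouts, means = extract_bouts(obs)
        assert [(b.label, b.duration_min) for b in bouts] == [
            ("grazing", 3), ("non_grazing", 2), ("grazing", 1)]
        assert means["grazing"] == pytest.approx(120.0)
        assert means["non_grazing"] == pytest.approx(120.0)

    def test_single_label_single_bout(self):
        obs = minutes("c1", T0, ["grazing"] * 10)
        bouts, _ = extract_bouts(obs)
        assert len(bouts) == 1
        assert bouts[0].duration_min == 10

    def test_session_gap_splits_bouts(self):
        obs = (minutes("c1", T0, ["grazing"] * 5)
               + minutes("c1", T0 + timedelta(hours=2), ["grazing"] * 5))
        bouts, _ = extract_bouts(obs)
        assert [b.duration_min for b in bouts] == [5, 5]

    def test_durations_conserve_labelled_minutes(self, small_observations):
        bouts, _ = extract_bouts(small_observations)
        for label in ("grazing", "non_grazing"):
            total = sum(b.duration_min for b in bouts if b.label == label)
            assert total == sum(o.label == label for o in small_observations)


class TestTemperatureComparison:
    def _sensor(self, hours, temps, animal="c1"):
        return [TemperatureSample(animal, T0 + timedelta(hours=h), c)
                for h, c in zip(hours, temps)]

    def test_identical_series(self):
        sensor = self._sensor(range(10), [10.0 + h for h in range(10)])
        station = pd.DataFrame({
            "time": [T0 + timedelta(hours=h) for h in range(10)],
            "temp_c": [10.0 + h for h in range(10)],
        })
        result = series_compare_temperature(sensor, station)
        assert result.rho == pytest.approx(1.0)
        assert result.mean_offset_c == pytest.approx(0.0)

    def test_constant_shift(self):
        sensor = self._sensor(range(10), [10.0 + h for h in range(10)])
        station = pd.DataFrame({
            "time": [T0 + timedelta(hours=h) for h in range(10)],
            "temp_c": [8.0 + h for h in range(10)],
        })
        result = series_compare_temperature(sensor, station)
        assert result.rho == pytest.approx(1.0)
        assert result.mean_offset_c == pytest.approx(2.0)

    def test_disjoint_ranges_error(self):
        sensor = self._sensor(range(5), [10.0] * 5)
        station = pd.DataFrame({
            "time": [T0 + timedelta(days=30, hours=h) for h in range(5)],
            "temp_c": [10.0] * 5,
        })
        with pytest.raises(ValueError):
            series_compare_temperature(sensor, station)

    def test_sensor_averaged_within_hour(self):
        sensor = self._sensor([0, 0.5, 1, 2], [10.0, 12.0, 20.0, 25.0])
        station = pd.DataFrame({
            "time": [T0, T0 + timedelta(hours=1), T0 + timedelta(hours=2)],
            "temp_c": [11.0, 20.0, 25.0],
        })
        result = series_compare_temperature(sensor, station)
        assert result.hourly["sensor_c"].iloc[0] == pytest.approx(11.0)
        assert result.mean_offset_c == pytest.approx(0.0)
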