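"""Filtering and weighted aggregation against hand-computed and brute-force oracles."""

import dataclasses
import datetime as dt
import math

import numpy as np
import pytest

from greenfeedtools import (
    DailyAverage,
    GridRow,
    ProcessParams,
    StudyWindow,
    daily_averages,
    filter_min_time,
    grid_correlation,
    param_grid,
    process,
    remove_gas_outliers,
    simulate_trial,
    summarize_gas,
    weekly_averages,
)

from conftest import make_record


class TestMinTimeFilter:
    def test_empty_input(self):
        assert filter_min_time([], 2.0) == []

    def test_boundary_is_inclusive(self):
        r = make_record(duration_min=2.0)
        assert filter_min_time([r], 2.0) == [r]
        assert filter_min_time([make_record(duration_min=1.99)], 2.0) == []

    def test_matches_brute_force_on_simulation(self, paper_trial):
        records = paper_trial[0][:1000]
        kept = filter_min_time(records, 2.0)
        assert len(kept) == sum(1 for r in records if r.good_duration_min >= 2.0)
        assert all(r.good_duration_min >= 2.0 for r in kept)


class TestOutlierRemoval:
    def test_identical_values_nothing_masked(self):
        records = [make_record(gas={"CH4": 300.0}) for _ in range(10)]
        out = remove_gas_outliers(records, 3.0)
        assert len(out) == 10 and all(r.gas["CH4"] == 300.0 for r in out)

    def test_single_value_sd_undefined_no_masking(self):
        records = [make_record(gas={"CH4": 1e6, "CO2": 12000.0}),
                   make_record(gas={"CO2": 12100.0})]
        out = remove_gas_outliers(records, 3.0)
        assert out[0].gas["CH4"] == 1e6  # only one CH4 value: left alone

    def test_extreme_value_masked_band_checked_explicitly(self):
        vals = [300.0] * 99 + [10_000.0]
        records = [make_record(animal=f"A{i}", gas={"CH4": v})
                   for i, v in enumerate(vals)]
        mean = np.mean(vals)
        sd = np.std(vals, ddof=1)
        assert abs(10_000 - mean) > 3 * sd and abs(300 - mean) <= 3 * sd
        out = remove_gas_outliers(records, 3.0)
        kept_vals = [r.gas["CH4"] for r in out]
        assert kept_vals == [300.0] * 99  # all-missing record dropped

    def test_masking_is_per_gas(self):
        records = [make_record(gas={"CH4": 300.0, "CO2": 12000.0 + 10.0 * i})
                   for i in range(50)]
        records.append(make_record(gas={"CH4": 10_000.0, "CO2": 12250.0}))
        out = remove_gas_outliers(records, 3.0)
        assert len(out) == 51
        assert "CH4" not in out[-1].gas and out[-1].gas["CO2"] == 12250.0

    def test_single_pass_statistics(self):
        # 9000 would fall outside the band recomputed after masking 10000;
        # a single global pass must keep it.
        vals = [300.0] * 200 + [9_000.0, 50_000.0]
        mean, sd = np.mean(vals), np.std(vals, ddof=1)
        assert abs(9000 - mean) <= 3 * sd < abs(50_000 - mean)
        records = [make_record(animal=f"A{i}", gas={"CH4": v})
                   for i, v in enumerate(vals)]
        kept = [r.gas["CH4"] for r in remove_gas_outliers(records, 3.0)]
        assert 9_000.0 in kept and 50_000.0 not in kept


class TestDailyAverages:
    def test_hand_computed_weighted_mean(self):
        records = [
            make_record(duration_min=2.0, gas={"CH4": 300.0}),
            make_record(start="2024-01-15 12:00:00", duration_min=4.0,
                        gas={"CH4": 360.0}),
        ]
        (day,) = daily_averages(records, param1=2)
        assert day.gas_mean["CH4"] == pytest.approx((2 * 300 + 4 * 360) / 6)
        assert day.n_records == 2 and day.total_minutes == 6.0

    def test_param1_threshold_suppresses_group(self):
        assert daily_averages([make_record()], param1=2) == []

    def test_gas_missing_never_zero(self):
        records = [make_record(gas={"CO2": 12000.0}),
                   make_record(start="2024-01-15 13:00:00", gas={"CO2": 12100.0})]
        (day,) = daily_averages(records, param1=2)
        assert "CH4" not in day.gas_mean

    def test_equal_durations_reduce_to_arithmetic_mean(self):
        rng = np.random.default_rng(42)
        for i in range(500):
            n = int(rng.integers(2, 6))
            vals = rng.uniform(100, 700, n)
            records = [
                make_record(animal=f"G{i}", start=f"2024-01-15 {7 + k:02d}:00:00",
                            duration_min=3.0, gas={"CH4": float(v)})
                for k, v in enumerate(vals)
            ]
            (day,) = daily_averages(records, param1=1)
            assert day.gas_mean["CH4"] == pytest.approx(vals.mean(), rel=1e-12)


class TestWeeklyAverages:
    def test_equal_weights_hand_example(self, week_window):
        daily = [
            DailyAverage("A1", dt.date(2024, 1, 15 + k), 2, 10.0,
                         {"CH4": 360.0 + 10 * k})
            for k in range(4)
        ]
        (week,) = weekly_averages(daily, param2=4, study=week_window)
        assert week.gas_mean["CH4"] == pytest.approx(375.0)
        assert week.week_index == 1 and week.n_days == 4

    def test_param2_threshold(self, week_window):
        daily = [
            DailyAverage("A1", dt.date(2024, 1, 15 + k), 2, 10.0, {"CH4": 370.0})
            for k in range(3)
        ]
        assert weekly_averages(daily, param2=4, study=week_window) == []

    def test_minute_weighting(self, week_window):
        daily = [
            DailyAverage("A1", dt.date(2024, 1, 15), 2, 2.0, {"CH4": 300.0}),
            DailyAverage("A1", dt.date(2024, 1, 16), 2, 6.0, {"CH4": 400.0}),
        ]
        (week,) = weekly_averages(daily, param2=2, study=week_window)
        assert week.gas_mean["CH4"] == pytest.approx((2 * 300 + 6 * 400) / 8)


class TestProcess:
    PARAMS = ProcessParams(param1=2, param2=4, min_time=2.0)

    def test_empty_records(self, week_window):
        result = process([], self.PARAMS, week_window)
        assert result.daily == [] and result.weekly == []

    def test_noiseless_pipeline_is_exact(self, week_window):
        records = [
            make_record(start=f"2024-01-{15 + d:02d} {8 + 2 * k:02d}:00:00",
                        duration_min=3.0, gas={"CH4": 375.0})
            for d in range(7)
            for k in range(3)
        ]
        result = process(records, self.PARAMS, week_window)
        assert len(result.daily) == 7 and len(result.weekly) == 1
        assert all(d.gas_mean["CH4"] == 375.0 for d in result.daily)
        assert result.weekly[0].gas_mean["CH4"] == 375.0

    def test_composition_equals_manual_stages(self, paper_cfg):
        records = simulate_trial(dataclasses.replace(paper_cfg, seed=21))[0][:2000]
        study = paper_cfg.study
        result = process(records, self.PARAMS, study)
        manual = weekly_averages(
            daily_averages(
                remove_gas_outliers(filter_min_time(records, 2.0), 3.0), 2
            ),
            4,
            study,
        )
        assert result.weekly == manual
        assert result.counts["records_in"] == 2000
        assert (
            result.counts["after_min_time"]
            >= result.counts["after_outlier_removal"]
        )

    def test_min_time_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2 min"):
            ProcessParams(min_time=1.0)


class TestSummarizeGas:
    def test_single_value(self):
        s = summarize_gas([5.0])
        assert (s.n, s.mean, s.sd, s.cv) == (1, 5.0, 0.0, 0.0)

    def test_two_point_closed_form(self):
        s = summarize_gas([10.0, 20.0])
        assert s.mean == 15.0
        assert s.sd == pytest.approx(math.sqrt(50), rel=1e-12)
        assert s.cv == pytest.approx(100 * math.sqrt(50) / 15, rel=1e-12)
        assert (s.min, s.max) == (10.0, 20.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_gas([])

    def test_simulator_herd_mean(self, big_trial):
        s = summarize_gas([r.gas["CH4"] for r in big_trial[0]])
        assert abs(s.mean - 375) / 375 < 0.05


class TestParamGrid:
    def test_single_combination_consistent_with_process(self, paper_trial, paper_cfg):
        records = paper_trial[0]
        study = paper_cfg.study
        (row,) = param_grid(records, [2], [4], [2.0], study)
        result = process(records, ProcessParams(2, 4, 2.0), study)
        assert row.n_daily_records == len(result.daily)
        assert row.n_weekly_records == len(result.weekly)
        assert row.n_animals_daily == len({d.animal_id for d in result.daily})
        d_vals = [d.gas_mean["CH4"] for d in result.daily if "CH4" in d.gas_mean]
        assert row.daily_mean == pytest.approx(np.mean(d_vals))
        assert row.daily_sd == pytest.approx(np.std(d_vals, ddof=1))

    def test_counts_non_increasing_in_param1_and_min_time(self, paper_trial,
                                                          paper_cfg):
        records = paper_trial[0]
        grid = param_grid(records, [1, 2, 3], [4], [2.0, 3.0], paper_cfg.study)
        by = {(g.param1, g.min_time): g for g in grid}
        for mt in (2.0, 3.0):
            counts = [by[(p1, mt)].n_daily_records for p1 in (1, 2, 3)]
            assert counts == sorted(counts, reverse=True)
        for p1 in (1, 2, 3):
            assert by[(p1, 2.0)].n_daily_records >= by[(p1, 3.0)].n_daily_records

    def test_weekly_never_exceeds_daily(self, paper_trial, paper_cfg):
        grid = param_grid(paper_trial[0], [1, 2, 3], [3, 5, 7], [2.0],
                          paper_cfg.study)
        for row in grid:
            assert row.n_weekly_records <= row.n_daily_records
            assert row.n_animals_weekly <= row.n_animals_daily

    def test_empty_weekly_cell_reports_missing_mean(self, week_window):
        records = [
            make_record(start=f"2024-01-15 {8 + k:02d}:00:00", gas={"CH4": 350.0})
            for k in range(3)
        ]
        (row,) = param_grid(records, [1], [5], [2.0], week_window)
        assert row.n_weekly_records == 0 and row.weekly_mean is None


class TestGridCorrelation:
    @staticmethod
    def _grid(ys):
        return [
            GridRow(p1, p2, 2.0, y, 0, None, None, 0, 0, None, None)
            for (p1, p2), y in zip(
                [(a, b) for a in (1, 2, 3) for b in (3, 4, 5)], ys
            )
        ]

    def test_identity_gives_r_one(self):
        grid = self._grid([1, 1, 1, 2, 2, 2, 3, 3, 3])
        assert grid_correlation(grid, "param1", "n_daily_records") == pytest.approx(1.0)

    def test_decreasing_gives_negative_r(self):
        grid = self._grid([9, 8, 7, 6, 5, 4, 3, 2, 1])
        assert grid_correlation(grid, "param1", "n_daily_records") < 0

    def test_matches_textbook_formula(self):
        ys = [120, 90, 80, 70, 55, 50, 40, 30, 20]
        grid = self._grid(ys)
        xs = [g.param1 for g in grid]
        n = len(xs)
        sx, sy = sum(xs), sum(ys)
        sxy = sum(x * y for x, y in zip(xs, ys))
        sxx, syy = sum(x * x for x in xs), sum(y * y for y in ys)
        expected = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx**2) * (n * syy - sy**2)
        )
        assert grid_correlation(grid, "param1", "n_daily_records") == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_variance_undefined(self):
        grid = self._grid([5] * 9)
        assert grid_correlation(grid, "param1", "n_daily_records") is None
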