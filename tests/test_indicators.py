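"""Indicator engine: windows, raw metrics vs brute force, normalization,
drought calibration, and panel behaviour under targeted perturbations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wezmap as wz
from wezmap.indicators import (
    Condition,
    NormalizationSpec,
    WindowSpec,
    count_condition_days,
    default_catalog,
    drought_threshold_q1,
    max_run_length,
    normalize,
    phase_deficit,
    phase_window,
    water_balance_series,
    catalog_to_yaml,
    catalog_from_yaml,
)

from conftest import make_constant_weather, make_stage_row


class TestPhaseWindow:
    def test_stage_to_offset_anchor(self):
        row = make_stage_row().iloc[0]
        row["E1"] = pd.Timestamp("2000-03-20")
        row["AN"] = pd.Timestamp("2000-06-01")
        start, end = phase_window(row, WindowSpec("E1", 0, "AN", 10))
        assert start == pd.Timestamp("2000-03-20")
        assert end == pd.Timestamp("2000-06-11")

    def test_meiosis_proxy_window_is_11_days(self):
        row = make_stage_row().iloc[0]
        start, end = phase_window(row, WindowSpec("FL", -5, "FL", 5))
        assert (end - start).days == 10
        assert start == row["FL"] - pd.Timedelta(days=5)

    def test_missing_anchor_returns_none(self):
        row = make_stage_row().iloc[0]
        row["AN"] = pd.NaT
        assert phase_window(row, WindowSpec("FL", 0, "AN")) is None


class TestRawMetrics:
    def _frame(self, tavg):
        dates = pd.date_range("2000-01-01", periods=len(tavg))
        return pd.DataFrame({"tavg": tavg}, index=dates, dtype=float)

    def test_count_zero_when_no_day_qualifies(self):
        f = self._frame([6.0] * 10)
        assert count_condition_days(f, [Condition("tavg", "lt", 5.0)]) == 0

    def test_count_fifteen_cold_days_in_twenty(self):
        f = self._frame([2.0] * 15 + [8.0] * 5)
        assert count_condition_days(f, [Condition("tavg", "lt", 5.0)]) == 15

    def test_compound_condition_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        n = 60
        dates = pd.date_range("2000-01-01", periods=n)
        f = pd.DataFrame({"tmin": rng.uniform(-5, 10, n),
                          "radiation": rng.uniform(50, 400, n)}, index=dates)
        conds = [Condition("tmin", "lt", 4.0), Condition("radiation", "lt", 200.0)]
        expect = sum(1 for i in range(n)
                     if f["tmin"].iloc[i] < 4.0 and f["radiation"].iloc[i] < 200.0)
        assert count_condition_days(f, conds) == expect

    def test_run_length_hand_trace(self):
        # pattern TTFTTTTT -> longest run 5
        f = self._frame([1.0, 1.0, 9.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        assert max_run_length(f, [Condition("tavg", "lt", 5.0)]) == 5

    def test_run_length_zero_when_never_satisfied(self):
        f = self._frame([9.0] * 8)
        assert max_run_length(f, [Condition("tavg", "lt", 5.0)]) == 0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(bits=st.lists(st.booleans(), min_size=1, max_size=80))
    def test_run_length_matches_brute_force(self, bits):
        f = self._frame([1.0 if b else 9.0 for b in bits])
        best = cur = 0
        for b in bits:
            cur = cur + 1 if b else 0
            best = max(best, cur)
        assert max_run_length(f, [Condition("tavg", "lt", 5.0)]) == best


class TestWaterBalance:
    def _weather(self, p_minus_pet):
        dates = pd.date_range("2000-01-01", periods=len(p_minus_pet))
        pp = np.asarray(p_minus_pet, dtype=float)
        return pd.DataFrame({"precip": np.maximum(pp, 0.0),
                             "pet": np.maximum(-pp, 0.0)}, index=dates)

    def test_zero_when_precip_equals_pet(self):
        dates = pd.date_range("2000-01-01", periods=5)
        w = pd.DataFrame({"precip": 2.0, "pet": 2.0}, index=dates)
        assert (water_balance_series(w, 2000) == 0).all()

    def test_toy_cumulative_series(self):
        w = self._weather([2, -1, -1, -3, 1])
        assert water_balance_series(w, 2000).tolist() == [2, 1, 0, -3, -2]

    def test_phase_deficit_toy_window(self):
        w = self._weather([2, -1, -1, -3, 1])
        window = (pd.Timestamp("2000-01-02"), pd.Timestamp("2000-01-04"))
        assert phase_deficit(w, window) == -5.0

    def test_phase_sums_partition_season_total(self):
        rng = np.random.default_rng(8)
        w = self._weather(rng.normal(0, 2, 90))
        cuts = [0, 20, 45, 60, 90]
        dates = w.index
        parts = [
            phase_deficit(w, (dates[a], dates[b - 1]))
            for a, b in zip(cuts, cuts[1:])
        ]
        total = phase_deficit(w, (dates[0], dates[-1]))
        assert sum(parts) == pytest.approx(total)

    def test_drier_scenario_strictly_smaller_deficit(self):
        w = self._weather([2, -1, 3, -3, 1])
        halved = w.assign(precip=w["precip"] * 0.5)
        win = (w.index[0], w.index[-1])
        assert phase_deficit(halved, win) < phase_deficit(w, win)

    def test_missing_january_coverage_raises(self):
        w = self._weather([1, 2, 3])
        with pytest.raises(ValueError, match="1 Jan"):
            water_balance_series(w, 1999)


class TestQuartileThreshold:
    def test_linear_interpolation_rule(self):
        assert drought_threshold_q1([1, 2, 3, 4]) == pytest.approx(1.75)

    def test_constant_values(self):
        assert drought_threshold_q1([5.0] * 10) == 5.0

    def test_matches_sort_based_oracle_on_pooled_values(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(-50, 30, 60)  # 2 cells x 30 seasons pooled
        # type-7 quartile by hand: sorted, h = (n-1) * 0.25
        s = np.sort(vals)
        h = (len(s) - 1) * 0.25
        lo = int(np.floor(h))
        expect = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
        assert drought_threshold_q1(vals) == pytest.approx(expect)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="4"):
            drought_threshold_q1([1.0, 2.0, 3.0])


class TestNormalize:
    def test_exponential_no_stress_is_one(self):
        spec = NormalizationSpec("negative_exponential", anchor=(15, 0.55))
        assert normalize(0.0, spec) == 1.0

    def test_worked_example_anchor(self):
        spec = NormalizationSpec("negative_exponential", anchor=(15, 0.55))
        assert normalize(15.0, spec) == pytest.approx(0.55, abs=1e-12)

    def test_double_raw_squares_the_anchor_value(self):
        spec = NormalizationSpec("negative_exponential", anchor=(15, 0.55))
        assert normalize(30.0, spec) == pytest.approx(0.3025, abs=1e-9)

    def test_negative_raw_rejected_for_exponential(self):
        spec = NormalizationSpec("negative_exponential", anchor=(15, 0.55))
        with pytest.raises(ValueError):
            normalize(-1.0, spec)

    def test_sigmoid_midpoint_is_half(self):
        spec = NormalizationSpec("sigmoid", x0=-40.0, s=0.05)
        assert normalize(-40.0, spec) == pytest.approx(0.5)

    def test_uncalibrated_sigmoid_rejected(self):
        spec = NormalizationSpec("sigmoid", calibrate="q1")
        with pytest.raises(ValueError, match="uncalibrated"):
            normalize(-10.0, spec)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(raw=st.floats(0.0, 60.0), delta=st.floats(0.01, 20.0))
    def test_exponential_monotone_decreasing(self, raw, delta):
        spec = NormalizationSpec("negative_exponential", anchor=(5, 0.5))
        assert normalize(raw + delta, spec) < normalize(raw, spec) + 1e-12

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(raw=st.floats(-200.0, 200.0), delta=st.floats(0.01, 50.0))
    def test_sigmoid_monotone_with_water_balance(self, raw, delta):
        # drier (smaller raw) never scores better
        spec = NormalizationSpec("sigmoid", x0=-40.0, s=0.05)
        assert normalize(raw - delta, spec) <= normalize(raw, spec) + 1e-12


BENIGN_CALIBRATION = {
    f"{tag}_drought": (-1000.0, 0.05)
    for tag in ("soem", "eme1", "e1fl", "flan", "angm")
}


class TestPanel:
    def test_benign_climate_all_values_one(self, fixed_stages):
        # mild, dry-but-calm weather exceeding no stress threshold, drought
        # normalization frozen from a far-drier reference
        g = make_constant_weather(tavg=12.0, spread=4.0, precip=0.0, pet=0.2)
        panel = wz.compute_panel(g, fixed_stages, default_catalog(),
                                 calibration=BENIGN_CALIBRATION)
        assert np.allclose(panel.values["value"], 1.0, atol=1e-6)

    def test_heatwave_hits_flan_heat_indicator_only(self, fixed_stages):
        g = make_constant_weather(tavg=12.0, spread=4.0, precip=0.0, pet=0.2)
        frame = g.frame.copy()
        days = pd.date_range("2000-04-20", periods=3)  # inside FL–AN
        for d in days:
            frame.loc[("cell", d), ["tmax", "tavg", "tmin"]] = [35.0, 27.0, 19.0]
        g2 = wz.WeatherGrid(frame=frame, cells=g.cells)
        panel = wz.compute_panel(g2, fixed_stages, default_catalog(),
                                 calibration=BENIGN_CALIBRATION)
        v = panel.values.set_index("indicator")["value"]
        assert v["flan_heat_days"] < 1.0
        assert v["angm_heat_days"] == 1.0
        assert v["eme1_cold_days"] == 1.0

    @pytest.mark.parametrize("indicator,perturb", [
        ("soem_flood_run", {"var": "precip", "value": 15.0, "start": "1999-10-20", "n": 6}),
        ("soem_cold_run", {"var": "tavg", "value": 0.0, "start": "1999-10-20", "n": 4}),
        ("soem_frost_days", {"var": "tmin", "value": -7.0, "start": "1999-10-20", "n": 3}),
        ("eme1_cold_days", {"var": "tavg", "value": 3.0, "start": "1999-12-01", "n": 10}),
        ("eme1_freeze_run", {"var": "tavg", "value": -1.0, "start": "1999-12-01", "n": 5}),
        ("eme1_frost_days", {"var": "tmin", "value": -10.0, "start": "1999-12-01", "n": 3}),
        ("vern_pause_days", {"var": "tavg", "value": 18.0, "start": "1999-12-01", "n": 8}),
        ("devern_days", {"var": "tavg", "value": 22.0, "start": "1999-12-01", "n": 4}),
        ("e1fl_cold_days", {"var": "tmin", "value": -1.0, "start": "2000-03-10", "n": 5}),
        ("e1fl_frost_days", {"var": "tmin", "value": -6.0, "start": "2000-03-10", "n": 3}),
        ("meiosis_cold_lowrad", {"var": "radiation", "value": 100.0,
                                 "start": "2000-04-12", "n": 4, "var2": "tmin", "value2": 2.0}),
        ("warm_nights", {"var": "tmin", "value": 14.0, "start": "2000-03-15", "n": 8,
                         "var2": "tavg", "value2": 16.0}),
        ("flan_heat_days", {"var": "tmax", "value": 32.0, "start": "2000-04-20", "n": 3}),
        ("angm_heat_days", {"var": "tmax", "value": 32.0, "start": "2000-06-01", "n": 4}),
        ("angm_cold_band", {"var": "tmin", "value": -4.0, "start": "2000-06-01", "n": 2}),
        ("eme1_drought", {"var": "pet", "value": 6.0, "start": "1999-12-01", "n": 40}),
        ("eme1_wet_run", {"var": "precip", "value": 12.0, "start": "1999-12-01", "n": 12}),
        ("e1fl_wet_run", {"var": "precip", "value": 12.0, "start": "2000-03-10", "n": 12}),
        ("flan_wet_run", {"var": "precip", "value": 12.0, "start": "2000-04-20", "n": 12}),
        ("angm_wet_run", {"var": "precip", "value": 12.0, "start": "2000-06-01", "n": 12}),
        ("soem_drought", {"var": "pet", "value": 8.0, "start": "1999-10-17", "n": 10}),
        ("e1fl_drought", {"var": "pet", "value": 8.0, "start": "2000-03-10", "n": 30}),
        ("flan_drought", {"var": "pet", "value": 8.0, "start": "2000-04-18", "n": 20}),
        ("angm_drought", {"var": "pet", "value": 8.0, "start": "2000-05-15", "n": 40}),
    ])
    def test_every_default_indicator_responds_to_its_perturbation(
            self, fixed_stages, indicator, perturb):
        base = make_constant_weather(tavg=10.0, spread=4.0, precip=0.0, pet=0.5)
        calib = {k: (-370.0, 0.05) for k in BENIGN_CALIBRATION}  # near base raws
        cat = default_catalog()
        ref = wz.compute_panel(base, fixed_stages, cat, calibration=calib)
        frame = base.frame.copy()
        days = pd.date_range(perturb["start"], periods=perturb["n"])
        for d in days:
            frame.loc[("cell", d), perturb["var"]] = perturb["value"]
            if "var2" in perturb:
                frame.loc[("cell", d), perturb["var2"]] = perturb["value2"]
        # keep tmin <= tavg <= tmax consistent after temperature edits
        frame["tmin"] = np.minimum(frame["tmin"], frame["tavg"])
        frame["tmax"] = np.maximum(frame["tmax"], frame["tavg"])
        g2 = wz.WeatherGrid(frame=frame, cells=base.cells)
        panel = wz.compute_panel(g2, fixed_stages, default_catalog(), calibration=calib)
        v0 = ref.values.set_index("indicator")["value"][indicator]
        v1 = panel.values.set_index("indicator")["value"][indicator]
        assert v1 < v0

    def test_missingness_matches_incomplete_cycles(self, small_grid, params):
        # truncate the calendar so late seasons cannot complete
        cut = small_grid.frame.index.get_level_values("date") <= pd.Timestamp("1996-05-01")
        g = wz.WeatherGrid(frame=small_grid.frame[cut], cells=small_grid.cells)
        stages = wz.simulate_grid(g, params, [1993, 1994, 1995, 1996])
        panel = wz.compute_panel(g, stages, default_catalog(), calibrate=True)
        miss = panel.values["value"].isna().groupby(
            [panel.values["cell_id"], panel.values["season"]]).any()
        incomplete = ~stages.frame["completed"]
        assert (miss.loc[incomplete.index] == incomplete).all()

    def test_duplicate_catalog_ids_rejected(self, fixed_stages):
        g = make_constant_weather()
        cat = default_catalog()
        cat.append(cat[0])
        with pytest.raises(ValueError, match="duplicate"):
            wz.compute_panel(g, fixed_stages, cat, calibration=BENIGN_CALIBRATION)

    def test_uncalibrated_drought_on_future_period_rejected(self, fixed_stages):
        g = make_constant_weather()
        with pytest.raises(ValueError, match="uncalibrated"):
            wz.compute_panel(g, fixed_stages, default_catalog(),
                             calibrate=False, period="near_future")

    def test_panel_recomputation_identical(self, small_grid, stages):
        cat = default_catalog()
        p1 = wz.compute_panel(small_grid, stages, cat, calibrate=True)
        p2 = wz.compute_panel(small_grid, stages, wz.default_catalog(), calibrate=True)
        pd.testing.assert_frame_equal(p1.values, p2.values)

    def test_calibration_freezing_reproduces_reference_values(self, small_grid, stages):
        cat = default_catalog()
        ref = wz.compute_panel(small_grid, stages, cat, calibrate=True)
        again = wz.compute_panel(small_grid, stages, wz.default_catalog(),
                                 calibration=ref.calibration, period="future")
        pd.testing.assert_frame_equal(ref.values, again.values)


class TestCatalogYaml:
    def test_round_trip(self, tmp_path):
        cat = default_catalog()
        catalog_to_yaml(cat, tmp_path / "cat.yaml")
        back = catalog_from_yaml(tmp_path / "cat.yaml")
        assert [s.id for s in back] == [s.id for s in cat]
        for a, b in zip(cat, back):
            assert a.family == b.family
            assert a.window == b.window
            assert a.aggregator == b.aggregator
            assert a.conditions == b.conditions
            if a.normalization.kind == "negative_exponential":
                assert b.normalization.k == pytest.approx(a.normalization.k)
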