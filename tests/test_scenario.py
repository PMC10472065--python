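"""Coupled scenario runs: forcing synthesis, variants, budgets, exports."""

import json

import numpy as np
import pandas as pd
import pytest

import racewaytwin as rt
from racewaytwin import DomainError, SyntheticForcingConfig, synthetic_forcing
from racewaytwin.scenario import ScenarioDefinition, export_scenario, run_scenario


def _run(make_config, variant, horizon_d, forcing=None, **overrides):
    cfg = make_config(
        scenario={"variant": variant, "name": variant, "horizon_d": horizon_d},
        **overrides)
    defn = ScenarioDefinition.from_config(cfg)
    if forcing is not None:
        defn.forcing = forcing
    return run_scenario(defn, cfg), cfg


class TestSyntheticForcing:
    def test_same_seed_reproduces_the_series(self):
        spec = SyntheticForcingConfig()
        a = synthetic_forcing(spec, 5, seed=42)
        b = synthetic_forcing(spec, 5, seed=42)
        np.testing.assert_array_equal(a.temperature_C, b.temperature_C)
        np.testing.assert_array_equal(a.inlet_DO_mgL, b.inlet_DO_mgL)

    def test_diurnal_cycle_shows_24h_periodicity(self):
        """Lag-24 autocorrelation of the detrended signal beats lag-17."""
        spec = SyntheticForcingConfig(noise_sd_temperature_C=0.05)
        series = synthetic_forcing(spec, 20, seed=3)
        x = series.temperature_C - np.convolve(
            series.temperature_C, np.ones(25) / 25, mode="same")
        x = x[24:-24]

        def acf(lag):
            return np.corrcoef(x[:-lag], x[lag:])[0, 1]

        assert acf(24) > acf(17)

    def test_zero_amplitudes_and_noise_give_constant_series(self):
        spec = SyntheticForcingConfig(
            seasonal_amplitude_C=0, diurnal_amplitude_C=0,
            inlet_do_diurnal_mgL=0, noise_sd_temperature_C=0,
            noise_sd_do_mgL=0, inlet_do_mean_mgL=10.0)
        series = synthetic_forcing(spec, 3, seed=0)
        assert np.ptp(series.temperature_C) == 0.0
        assert np.ptp(series.inlet_DO_mgL) == 0.0

    def test_parameters_producing_negative_do_rejected(self):
        spec = SyntheticForcingConfig(inlet_do_mean_mgL=0.1,
                                      inlet_do_diurnal_mgL=5.0,
                                      noise_sd_do_mgL=0.0)
        with pytest.raises(DomainError):
            synthetic_forcing(spec, 2, seed=0)

    def test_autumn_series_cools_toward_winter(self):
        import datetime

        spec = SyntheticForcingConfig(noise_sd_temperature_C=0.0)
        series = synthetic_forcing(spec, 60, seed=0,
                                   start_date=datetime.date(2019, 10, 1))
        daily = series.temperature_C[: 60 * 24].reshape(60, 24).mean(axis=1)
        assert daily[-1] < daily[0]


HEAVY_FISH = {"initial_count": 128000, "initial_mean_weight_g": 200,
              "initial_sd_weight_g": 30}


class TestScenarioVariants:
    def test_a_and_b_share_biomass_until_the_first_transfer(self, make_config):
        ra, _ = _run(make_config, "A", 40, fish=HEAVY_FISH)
        rb, _ = _run(make_config, "B", 40, fish=HEAVY_FISH)
        ta = [e for e in ra.events if e["kind"] == "transfer"][0]
        tb = [e for e in rb.events if e["kind"] == "transfer"][0]
        assert tb["day"] == ta["day"] + 7.0
        upto = ra.utilization_time_d <= ta["day"]
        np.testing.assert_allclose(ra.biomass_kg_by_day[upto],
                                   rb.biomass_kg_by_day[upto], rtol=1e-12)

    def test_transfer_drops_utilization_by_a_third(self, make_config):
        r, _ = _run(make_config, "A", 40, fish=HEAVY_FISH)
        day = int([e for e in r.events if e["kind"] == "transfer"][0]["day"])
        before = r.utilization_pct[day]
        after = r.utilization_pct[day + 1]
        # next-day utilization reflects the 1/3 removal plus one day's growth
        assert after < before * 0.72

    def test_b1_and_b2_differ_only_in_the_cutoff_week(self, make_config):
        r1, _ = _run(make_config, "B1", 40, fish=HEAVY_FISH)
        r2, _ = _run(make_config, "B2", 40, fish=HEAVY_FISH)
        c1 = [e for e in r1.events if e["kind"] == "supply_cutoff"][0]["time_h"]
        c2 = [e for e in r2.events if e["kind"] == "supply_cutoff"][0]["time_h"]
        assert c2 == c1 + 7 * 24
        np.testing.assert_allclose(r1.biomass_kg_by_day, r2.biomass_kg_by_day,
                                   rtol=1e-12)
        before = r1.budget.time_h <= c1
        np.testing.assert_allclose(r1.budget.outlet[before],
                                   r2.budget.outlet[before], rtol=1e-12)

    def test_empty_raceway_at_saturation_is_transparent(self, make_config):
        """No fish, no source, saturated inlet: outlet = inlet all run."""
        params = rt.ReaerationParams()
        cs = rt.csat(12.0, params)
        n = 2 * 24 + 1
        t = np.arange(n, dtype=float)
        forcing = rt.ForcingSeries(t, np.full(n, 12.0), np.full(n, cs),
                                   np.full(n, 1.5e6))
        r, _ = _run(make_config, "none", 2, forcing=forcing,
                    fish={"initial_count": 0.0, "initial_mean_weight_g": 100,
                          "initial_sd_weight_g": 0})
        np.testing.assert_allclose(r.budget.outlet, r.budget.inlet, atol=1e-9)

    def test_summer_snapshot_shows_diurnal_cycle_and_downstream_decay(
            self, make_config):
        """A warm high-biomass run: outlet DO oscillates daily and every
        snapshot decreases monotonically downstream."""
        import datetime

        cfg = make_config(
            start_date=datetime.date(2019, 7, 3),
            fish={"initial_count": 60000, "initial_mean_weight_g": 250,
                  "initial_sd_weight_g": 0},
            forcing={"synthetic": {"mean_temperature_C": 13.0,
                                   "noise_sd_temperature_C": 0.0,
                                   "noise_sd_do_mgL": 0.0}},
            scenario={"variant": "none", "name": "july", "horizon_d": 10},
        )
        defn = ScenarioDefinition.from_config(cfg)
        r = run_scenario(defn, cfg)
        outlet = r.budget.outlet
        daily_span = outlet[: 10 * 24].reshape(10, 24)
        assert np.all(np.ptp(daily_span, axis=1) > 0.1)  # visible daily swing
        # skip the first residence time, then every snapshot decays in x
        assert np.all(np.diff(r.do_field.C[:, 3:], axis=0) <= 1e-9)


class TestBudget:
    def test_no_fish_means_no_respiration_component(self, make_config):
        r, _ = _run(make_config, "none", 2,
                    fish={"initial_count": 0.0, "initial_mean_weight_g": 100,
                          "initial_sd_weight_g": 0})
        np.testing.assert_array_equal(r.budget.respiration, 0.0)

    def test_saturated_water_has_no_reaeration_component(self, make_config, geometry):
        params = rt.ReaerationParams()
        cs = rt.csat(12.0, params)
        n = 49
        t = np.arange(n, dtype=float)
        forcing = rt.ForcingSeries(t, np.full(n, 12.0), np.full(n, cs),
                                   np.full(n, 1.5e6))
        r, _ = _run(make_config, "none", 2, forcing=forcing,
                    fish={"initial_count": 0.0, "initial_mean_weight_g": 100,
                          "initial_sd_weight_g": 0})
        np.testing.assert_allclose(r.budget.reaeration, 0.0, atol=1e-9)

    def test_component_sum_closes_under_quasi_steady_conditions(self, make_config):
        n = 3 * 24 + 1
        t = np.arange(n, dtype=float)
        forcing = rt.ForcingSeries(t, np.full(n, 12.0), np.full(n, 10.5),
                                   np.full(n, 1.5e6))
        r, _ = _run(make_config, "none", 3, forcing=forcing,
                    fish={"initial_count": 30000, "initial_mean_weight_g": 250,
                          "initial_sd_weight_g": 0})
        b = r.budget
        resid = b.outlet - (b.inlet + b.source + b.reaeration + b.respiration)
        assert np.all(np.abs(resid / b.outlet) < 0.02)

    def test_respiration_reported_as_negative_component(self, make_config):
        r, _ = _run(make_config, "none", 2,
                    fish={"initial_count": 30000, "initial_mean_weight_g": 250,
                          "initial_sd_weight_g": 0})
        assert np.all(r.budget.respiration < 0.0)


class TestExport:
    def test_scenario_export_writes_the_three_csvs(self, make_config, tmp_path):
        r, _ = _run(make_config, "A", 20, fish=HEAVY_FISH)
        paths = export_scenario(r, tmp_path)
        csvs = [p for p in paths if p.endswith(".csv")]
        assert len(csvs) == 3
        budget = pd.read_csv(tmp_path / "A_budget.csv")
        assert list(budget.columns) == ["time", "inlet", "outlet", "source",
                                        "reaeration", "respiration"]
        util = pd.read_csv(tmp_path / "A_utilization.csv")
        assert list(util.columns) == ["time", "utilization_pct", "scenario"]

    def test_refuses_to_overwrite_without_force(self, make_config, tmp_path):
        r, _ = _run(make_config, "none", 1)
        export_scenario(r, tmp_path)
        with pytest.raises(rt.RacewayError, match="force"):
            export_scenario(r, tmp_path)
        export_scenario(r, tmp_path, force=True)  # succeeds

    def test_event_log_is_json_lines(self, make_config, tmp_path):
        r, _ = _run(make_config, "A", 30, fish=HEAVY_FISH)
        export_scenario(r, tmp_path)
        lines = (tmp_path / "A_events.jsonl").read_text().splitlines()
        assert len(lines) == len(r.events)
        assert all(json.loads(l)["kind"] for l in lines)

    def test_identical_seed_gives_byte_identical_exports(self, make_config,
                                                         tmp_path):
        r1, _ = _run(make_config, "A", 15, fish=HEAVY_FISH)
        r2, _ = _run(make_config, "A", 15, fish=HEAVY_FISH)
        export_scenario(r1, tmp_path / "x")
        export_scenario(r2, tmp_path / "y")
        for name in ("A_utilization.csv", "A_do_field.csv", "A_budget.csv",
                     "A_events.jsonl"):
            assert (tmp_path / "x" / name).read_bytes() == \
                   (tmp_path / "y" / name).read_bytes()


class TestCrossModuleConsistency:
    def test_do_solver_sees_the_growth_modules_biomass(self, make_config):
        """The respiration sink on any day integrates to the biomass the
        growth module reports for that day."""
        from racewaytwin.bioenergetics import FeedPlan, metabolic_outputs

        r, cfg = _run(make_config, "A", 20, fish=HEAVY_FISH)
        geom = cfg.geometry
        plan = FeedPlan(feed=cfg.feed.spec, ration_frac_bw=cfg.feed.ration_frac_bw)
        for day in (0, 5, 12, 19):
            k = day * 24 + 3  # an hour inside that day
            w = r.growth.mean_weight_g[day]
            r_spec = metabolic_outputs(
                w, r.inputs.temperature_C[k], plan.intake_kJ(day, w),
                cfg.fish.params, cfg.feed.spec,
            ).respiration_mgO2_per_h / (w / 1000.0)
            # invert the solver's sink back to the biomass it encodes
            m_total = (r.inputs.sink_mgL_per_h[k][1] * geom.cross_section_m2
                       * 1000.0 * geom.length_m / r_spec)
            assert m_total == pytest.approx(r.biomass_kg_by_day[day], rel=1e-9)
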