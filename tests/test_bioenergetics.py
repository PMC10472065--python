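"""Energy-budget growth model: balance points, closed forms, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racewaytwin import (
    BioenergeticParams,
    DomainError,
    FeedPlan,
    FeedSpec,
    FishCohort,
    ForcingSeries,
    gross_energy,
    integrate_growth,
    max_ingestion,
    metabolic_outputs,
    weight_derivative,
)
from racewaytwin.bioenergetics import anabolism, catabolism, temperature_response

from conftest import constant_forcing


class TestGrossEnergy:
    def test_mass_weighted_sum(self):
        feed = FeedSpec(protein_frac=0.45, lipid_frac=0.25, carb_frac=0.15,
                        gross_energy_coeffs=(23.6, 39.5, 17.2))
        # 0.45·23.6 + 0.25·39.5 + 0.15·17.2
        assert gross_energy(feed) == pytest.approx(23.075)

    def test_empty_feed_has_zero_energy(self):
        assert gross_energy(FeedSpec(protein_frac=0, lipid_frac=0, carb_frac=0)) == 0.0

    def test_fractions_summing_above_one_rejected(self):
        with pytest.raises(Exception):
            FeedSpec(protein_frac=0.7, lipid_frac=0.5, carb_frac=0.0)


class TestWeightDerivative:
    def test_starvation_always_loses_weight(self, params):
        for W, T in [(10, 5), (100, 12), (500, 20)]:
            assert weight_derivative(W, T, 0.0, params) < 0

    def test_balance_point_gives_zero_derivative(self, params):
        W, T = 150.0, 12.0
        catab = catabolism(W, T, params)
        fa = temperature_response(T, params)
        intake = catab / (params.assimilation_eff * fa)
        assert intake < max_ingestion(W, T, params)  # ration-limited regime
        assert weight_derivative(W, T, intake, params) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_weight_rejected(self, params):
        with pytest.raises(DomainError):
            weight_derivative(0.0, 12.0, 10.0, params)

    def test_starvation_with_linear_catabolism_matches_exponential(self, params):
        """n = 1 starvation is a linear ODE: W(t) = W0·exp(−k_C e^{p_k T} t)."""
        p = params.model_copy(update={"catab_exponent": 1.0})
        T = 12.0
        forcing = constant_forcing(31 * 24, T=T)
        traj = integrate_growth(
            FishCohort(count=1, mean_weight_g=300.0), forcing,
            FeedPlan(ration_g_per_fish=0.0), p, dt_d=1.0, horizon_d=30,
        )
        k = p.catab_coeff * np.exp(p.catab_temp_coeff * T)
        expected = 300.0 * np.exp(-k * traj.time_d)
        np.testing.assert_allclose(traj.mean_weight_g, expected, rtol=1e-3)


class TestMaxIngestion:
    def test_zero_at_thermal_maximum(self, params):
        assert max_ingestion(200.0, params.anab_temp_max, params) == 0.0

    def test_two_thirds_allometry(self, params):
        r = max_ingestion(400.0, 14.0, params) / max_ingestion(200.0, 14.0, params)
        assert r == pytest.approx(2 ** (2.0 / 3.0), rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1.0, 2000.0), st.floats(-1.0, 39.0))
    def test_cap_non_negative_on_domain(self, W, T):
        assert max_ingestion(W, T, BioenergeticParams()) >= 0.0


class TestMetabolicOutputs:
    def test_feeding_raises_respiration_above_fasting(self, params):
        fasting = metabolic_outputs(200.0, 12.0, 0.0, params)
        fed = metabolic_outputs(200.0, 12.0, 60.0, params)
        assert fed.respiration_mgO2_per_h > fasting.respiration_mgO2_per_h

    def test_fasting_respiration_linear_in_weight_when_n_is_one(self, params):
        p = params.model_copy(update={"catab_exponent": 1.0})
        r1 = metabolic_outputs(100.0, 12.0, 0.0, p).respiration_mgO2_per_h
        r2 = metabolic_outputs(200.0, 12.0, 0.0, p).respiration_mgO2_per_h
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_outputs_vanish_with_weight(self, params):
        out = metabolic_outputs(1e-9, 12.0, 0.0, params)
        assert 0.0 <= out.respiration_mgO2_per_h < 1e-8
        assert 0.0 <= out.tan_g_per_d < 1e-8
        assert 0.0 <= out.co2_g_per_d < 1e-8

    def test_respiration_nondecreasing_in_temperature_below_optimum(self, params):
        temps = np.linspace(0.0, params.anab_temp_optimum, 30)
        resp = [metabolic_outputs(200.0, t, 50.0, params).respiration_mgO2_per_h
                for t in temps]
        assert np.all(np.diff(resp) >= 0)


class TestIntegrateGrowth:
    def test_zero_horizon_returns_initial_state(self, params, feed_plan, cohort):
        forcing = constant_forcing(24)
        traj = integrate_growth(cohort, forcing, feed_plan, params, horizon_d=0)
        assert len(traj) == 1
        assert traj.mean_weight_g[0] == cohort.mean_weight_g
        assert traj.biomass_kg[0] == pytest.approx(cohort.biomass_kg)

    def test_step_count_matches_a_growing_season(self, params, feed_plan, cohort):
        forcing = constant_forcing(135 * 24)
        traj = integrate_growth(cohort, forcing, feed_plan, params, horizon_d=135)
        assert len(traj) == 136  # 135 daily steps plus the initial state

    def test_ad_libitum_growth_at_optimum_is_strictly_increasing(self, params):
        forcing = constant_forcing(60 * 24, T=params.anab_temp_optimum)
        plan = FeedPlan(ration_frac_bw=0.05)  # well above the ingestion cap
        traj = integrate_growth(FishCohort(count=100, mean_weight_g=50.0),
                                forcing, plan, params, horizon_d=60)
        assert np.all(np.diff(traj.mean_weight_g) > 0)
        # sign agrees with the instantaneous budget at every step
        for w in traj.mean_weight_g:
            assert weight_derivative(w, params.anab_temp_optimum,
                                     plan.intake_kJ(0, w), params) > 0

    def test_energy_conservation_over_the_run(self, params, feed_plan):
        """Fish energy gain + catabolised energy = assimilated intake."""
        forcing = constant_forcing(40 * 24, T=13.0)
        traj = integrate_growth(FishCohort(count=1, mean_weight_g=120.0),
                                forcing, feed_plan, params, horizon_d=40)
        gain = (traj.mean_weight_g[-1] - traj.mean_weight_g[0]) * params.fish_energy_density
        balance = traj.assimilated_kJ[-1] - traj.catabolised_kJ[-1]
        assert gain == pytest.approx(balance, rel=1e-6)

    def test_larger_ration_never_yields_smaller_fish(self, params):
        forcing = constant_forcing(30 * 24, T=12.0)
        lo = integrate_growth(FishCohort(count=1, mean_weight_g=100.0), forcing,
                              FeedPlan(ration_frac_bw=0.01), params, horizon_d=30)
        hi = integrate_growth(FishCohort(count=1, mean_weight_g=100.0), forcing,
                              FeedPlan(ration_frac_bw=0.02), params, horizon_d=30)
        assert np.all(hi.mean_weight_g >= lo.mean_weight_g)

    def test_biomass_equals_count_times_weight_without_spread(self, params, feed_plan):
        forcing = constant_forcing(20 * 24)
        traj = integrate_growth(FishCohort(count=1000, mean_weight_g=150.0,
                                           sd_weight_g=0.0),
                                forcing, feed_plan, params, horizon_d=20)
        np.testing.assert_allclose(
            traj.biomass_kg, 1000 * traj.mean_weight_g / 1000.0, rtol=1e-12)
        np.testing.assert_allclose(traj.lo_weight_g, traj.mean_weight_g, rtol=1e-9)

    def test_mortality_reduces_count_before_growth(self, params, feed_plan, cohort):
        forcing = constant_forcing(10 * 24)
        traj = integrate_growth(cohort, forcing, feed_plan, params,
                                horizon_d=10, mortality_per_day=10.0)
        assert traj.count[-1] == pytest.approx(cohort.count - 100.0)

    def test_prolonged_starvation_flags_collapse(self, params):
        # sublinear catabolism (n < 1) reaches zero weight in finite time
        p = params.model_copy(update={"catab_coeff": 0.2,
                                      "catab_exponent": 2.0 / 3.0})
        forcing = constant_forcing(60 * 24, T=20.0)
        traj = integrate_growth(FishCohort(count=10, mean_weight_g=5.0), forcing,
                                FeedPlan(ration_g_per_fish=0.0), p, horizon_d=60)
        assert traj.starvation_collapse
        assert traj.collapse_step is not None

    def test_fingerling_reaches_commercial_size_in_a_season(self, params, feed_plan):
        """Sanity envelope: ~50 g fingerlings pass 300 g within ~135 days at 8–16 °C."""
        n = 135 * 24 + 1
        t = np.arange(n, dtype=float)
        T = 12.0 + 4.0 * np.sin(2 * np.pi * t / (135 * 24))
        forcing = ForcingSeries(t, T, np.full(n, 10.0), np.full(n, 1.5e6))
        traj = integrate_growth(FishCohort(count=1, mean_weight_g=50.0), forcing,
                                feed_plan, params, horizon_d=135)
        assert 300.0 <= traj.mean_weight_g[-1] <= 800.0
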