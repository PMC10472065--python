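# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `racewaytwin`, and states what the test suite does
and does not demonstrate.

## System and scope

The simulated object is a single flow-through raceway of a land-based trout
farm: river water enters at x = 0, receives a point source of gasified
liquid oxygen, flows down a long narrow basin stocked with a rainbow-trout
cohort, and returns to the river at x = L. The package simulates one basin;
series or parallel coupling of basins, hatchery stages, economics and
sensor hardware are out of scope. Two clocks drive the coupling: growth,
feeding and stocking decisions advance daily; DO transport and the supply
policy advance hourly, the natural scale of the ~1 h water residence time.
Biomass is held constant within a day — fish gain at most a few percent of
their weight per day, while the raceway exchanges its water volume roughly
24 times.

## Bioenergetic growth model

Weight change is the budget between assimilated feed energy and metabolic
losses (see README for the equations). Design choices:

* **Temperature response.** `f_A(T) = z·exp(1 − z)` with
  `z = (T_max − T)/(T_max − T_opt)`, clipped to zero for `T ≥ T_max`. It is
  1 at the optimum, unimodal, and exactly zero at the thermal maximum, which
  makes the "ingestion shuts down in hot water" behaviour structural rather
  than numerical.
* **Ration is binding, not appetite.** Intake is
  `min(supplied ration energy, k_I · W^m · f_A(T))`: the farmer's ration
  governs growth whenever it is below the allometric ingestion cap.
* **Respiration.** `oxycal · (C + sda_frac · I)` per day, i.e. basal plus
  feeding metabolism. TAN is `tan_per_protein` times the protein share of
  catabolised energy; CO2 is `co2_per_O2` (respiratory quotient 1) times
  respired mass.
* **Population band.** Three trajectories are integrated from the mean and
  mean ± 1 sd initial weights. This reproduces the mean-and-band view of
  cohort growth at minimal cost; it is not a distributional model and says
  nothing about skew or size-dependent competition.
* **Mortality** is an exogenous daily death count (an observing-phase
  input); there is no endogenous mortality model.

### Default trout parameters

The defaults are a generic parameterisation, selected once against sanity
envelopes — a 50 g fingerling passes commercial size (300–500 g) in a
~135-day season at 8–16 °C, and routine metabolism is of order
300 mg O2 kg⁻¹ h⁻¹ — not a fit to any particular farm. All are
config-overridable.

| parameter | value | units | meaning |
|---|---|---|---|
| `anab_coeff` (k_I) | 1.9 | kJ g⁻ᵐ d⁻¹ | max-ingestion scale |
| `anab_exponent` (m) | 2/3 | – | ingestion allometry |
| `catab_coeff` (k_C) | 0.01 | d⁻¹ | catabolic rate at 0 °C |
| `catab_exponent` (n) | 1.0 | – | catabolism allometry |
| `catab_temp_coeff` (p_k) | 0.05 | °C⁻¹ | catabolic Q10-style factor |
| `anab_temp_optimum` | 14 | °C | anabolic optimum |
| `anab_temp_max` | 24 | °C | ingestion shutdown |
| `assimilation_eff` | 0.7 | – | assimilated fraction of intake |
| `fish_energy_density` (ε) | 6.0 | kJ/g | tissue energy density |
| `oxycal_coeff` | 73.5 | mg O2/kJ | from 13.6 kJ per g O2 |
| `sda_frac` | 0.15 | – | feeding metabolism fraction |
| `protein_catab_frac` | 0.3 | – | protein share of catabolism |
| `tan_per_protein` | 0.092 | g/g | TAN per protein catabolised |
| `co2_per_O2` | 1.375 | g/g | respiratory quotient 1 |
| gross energy coeffs | 23.6 / 39.5 / 17.2 | kJ/g | protein / lipid / carbohydrate |

With n = 1 the starvation equation is linear, giving the exponential decay
closed form used as the integrator's oracle. Integration is fixed-step RK4
(default 1 day); the cumulative anabolism and catabolism integrals are
carried in the RK4 state, which makes the energy-conservation identity
(ΔW·ε = assimilated − catabolised) hold to round-off by construction and
testable at 1e-6.

## DO transport

`R` in the transport equation is interpreted as **specific respiration**
(mg O2 per kg biomass per hour), so the sink term
`R · (∂M/∂x) / (A·1000)` closes to mg L⁻¹ h⁻¹; this is the only reading of
the sink that is dimensionally consistent, and it ties the water model to
the growth model through one number per day (hourly re-evaluated against
temperature).

* **Saturation.** Benson–Krause freshwater formulation, valid on
  [0, 40] °C, scaled linearly by pressure (atm); salinity fixed at zero
  (Alpine river water).
* **Scheme.** Explicit first-order upwind on a node-centred grid (default
  101 nodes over 200 m). The equation has no diffusion term, so upwind
  needs no outflow condition; the inlet node is Dirichlet (river DO plus
  source increment). Sub-steps are chosen from the CFL bound with a 0.9
  safety factor; an explicitly requested step that violates CFL raises an
  error stating the largest admissible step. Effective grid spacing (not
  the nominal one) is used when the length is not a multiple of dx.
* **Conservation.** The discrete advective flux telescopes, so the scheme's
  oxygen budget (inflow + source + reaeration − outflow − respiration −
  storage) closes to machine precision; the test suite verifies this with
  an independent accountant on randomised configurations at 0.5%.
* **Anoxia.** Negative concentrations are clipped to zero and logged as
  events; they are a model outcome (overstocked open-loop scenarios), not
  an exception.
* **Oracles.** At steady state with k_rear = 0 and uniform biomass the
  profile is linear (upwind reproduces it exactly at the nodes); with zero
  biomass it is an exponential relaxation toward Csat (geometric vs
  exponential discrepancy ≪ 0.1% at default resolution).
* **Point source.** The 2.4 m³/h pilot-style supply is interpreted as
  gasified-oxygen volume at 1.429 kg/m³ (a liquid-phase reading would imply
  an implausible ~2.7 t O2/h), delivered at 90% transfer efficiency.
  Consistency: 2.4 × 1.429 × 0.9 ≈ 3.09 kg O2/h; if that adds ≈ 2 mg/L,
  the implied flow is ≈ 1.5×10⁶ L/h, which for a 200 × 8 × 1 m raceway
  gives a ≈ 1 h residence time. The raceway depth is never a published
  quantity; it is a required config input, and the worked examples assume
  1 m.
* `k_rear` defaults to 0.1 h⁻¹ (config-overridable); raceway reaeration
  rates are site-specific and no generic value is authoritative.

## Management rules

Utilization = biomass density / baseline (default 20 kg/m³, common
flow-through trout practice). The transfer planner finds the first forecast
day on which utilization reaches 100% and schedules a fractional transfer
(default 1/3 of individuals; per-fish weights unchanged) `lead_days`
(default 1) earlier, plus an optional delay (7 days for the B variants). A
crossing already inside the lead window triggers an immediate transfer with
a warning. Because individual growth does not depend on stocking here, the
post-transfer forecast is the pre-transfer one scaled by the surviving
count fraction, and planning iterates to catch repeat crossings. When
several intervention rules fire on the same day, irreversible actions come
first (harvest > transfer > feed change > feed quantity > oxygen). The
default feed table (three weight classes) is illustrative.

## Supply control

Open-loop policies read a piecewise-constant schedule. The closed-loop
policies invert the transport model by bisection on the supply rate over
[0, max_supply] to 1e-3 m³/h, against a forward prediction:

* **Prediction horizon** is one control interval *plus one residence time*,
  so each decision sees the full transit of every water parcel admitted
  under it. (A horizon of one control interval alone systematically
  under-protects: parcels admitted late in the interval complete their
  drawdown under the next decision, which cannot retroactively enrich
  them.)
* **Forecast forcing.** The controllers accept the forthcoming hourly
  forcing (the twin's model forecast) and predict through it; this makes
  the welfare guarantee structural — each parcel's whole transit is checked
  by the decision that admitted it — rather than dependent on forcing
  staleness. Without a forecast the current forcing is held constant.
* **Initialization.** A scenario starts on an operating raceway, so the
  t = 0 profile is the solver's converged steady state under hour-0 forcing
  with the supply the policy itself would choose (welfare: smallest supply
  holding the floor; green: outlet = inlet; open-loop: the scheduled rate).
  Starting from pristine river water instead would make the first residence
  time trivially infeasible for any controller.
* The **feedback** valve is proportional-only with clamping, the simplest
  embodiment of an error-driven valve; it converges within 0.1 mg/L of the
  setpoint for gains well below the stability bound (gain × process
  sensitivity < 2; the default 0.5 m³/h per mg/L is far inside it).
* Infeasible demands (floor above what max supply can achieve) complete
  with saturation flags in the event log, never silently.

## Synthetic forcing

The generator emulates an Alpine river boundary: temperature = mean (13 °C)
+ seasonal cosine (amplitude 6 °C, mid-July peak — an autumn start then
cools toward winter) + diurnal sine (0.8 °C) + Gaussian noise (sd 0.15 °C);
inlet DO tracks the saturation concentration at the generated temperature
(ratio 1.0) with its own diurnal term (0.3 mg/L) and noise (sd 0.1 mg/L);
flow is constant at 1.5×10⁶ L/h. All draws come from one seeded generator.
It does **not** emulate floods, turbidity, upstream oxygen demand, sensor
dropouts or flow variation, so passing tests demonstrate correct model
coupling and control under clean periodic forcing, not robustness to real
river data. Real forcing enters through the same CSV reader used for
sensor exports (sub-hourly rows averaged, gaps ≤ 3 steps interpolated,
longer gaps rejected).

## Demonstration scenarios

The preset study conditions (also used by `scripts/acceptance.py`):

* **Welfare demo** — 30 days from October 1st, 50 000 trout of 200 g
  (≈ 31% utilization) on the 200 × 8 × 1 m raceway; the unforced DO minimum
  falls ≈ 1 mg/L below the 9.5 mg/L floor, so the controller must act for
  most of the run. Reported: min DO over all nodes and hours (≈ the
  threshold when the floor binds).
* **Transfer demo** — 40 days, 128 000 trout of 200 g (80% utilization at
  start); growth triggers the Scenario-A transfer after about two weeks.
  Reported: peak utilization percentage up to and including the transfer
  day (just under 100% by construction of the one-day lead — the check is
  that the planner's lead actually beats the crossing).

## Known limitations

* One raceway, one cohort; no inter-basin fluxes.
* No DO feedback on ingestion or growth (water quality is an input to the
  fish model only through temperature); the hook exists where intake is
  computed.
* First-order upwind introduces numerical diffusion; acceptable because
  longitudinal mixing is not resolved anyway and the budget is exact.
* The sd band ignores growth-rate dispersion (same parameters for all three
  trajectories).
* TAN and CO2 are reported as loads, not transported along x.
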