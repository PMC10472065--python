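"""Scenario engine: couples growth, DO transport, management and control.

A scenario advances on two clocks. Growth, feeding and stocking decisions
run on a daily step; the DO solver and the oxygen-supply policy run hourly
(the raceway residence time is of order one hour, so biomass is effectively
frozen within a day while DO is not). The biomass the DO solver sees on any
day is exactly the growth module's output for that day, scaled by the
transfer events the management planner has scheduled.

Scenario variants follow the farm's October storyline: **A** transfers one
third of the stock one day before predicted 100% utilization; **B** applies
the same transfer one week later; **B1**/**B2** are B with the constant
2.4 m³/h open-loop oxygen supply interrupted on the A-transfer date or one
week after it; **green** and **welfare** run B's biomass under the
closed-loop policies.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .bioenergetics import FeedPlan, GrowthTrajectory, integrate_growth, metabolic_outputs
from .config import (
    FishCohort,
    ForcingSeries,
    RacewayGeometry,
    SimulationConfig,
)
from .control import (
    ControlDecision,
    ForecastSegment,
    RacewayControlState,
    SupplySchedule,
    feedback_step,
    green_supply,
    scheduled_supply,
    welfare_supply,
)
from .do_transport import (
    BiomassProfile,
    DOField,
    OxygenSource,
    ReaerationParams,
    advance_interval,
    csat,
    source_increment,
)
from .errors import DomainError, RacewayError
from .forcing import synthetic_forcing
from .io import _FLOAT_FMT, ensure_writable_dir, write_field_csv
from .management import TransferRule, plan_transfer

__all__ = [
    "ScenarioDefinition",
    "RunInputs",
    "DOBudget",
    "ScenarioResult",
    "run_scenario",
    "budget_decomposition",
    "export_scenario",
]

_OPEN_LOOP_VARIANTS = ("A", "B", "B1", "B2", "none")


@dataclass
class ScenarioDefinition:
    """One dated scenario run."""

    name: str
    variant: str = "A"
    horizon_d: float = 60.0
    cohort: Optional[FishCohort] = None
    feed_plan: Optional[FeedPlan] = None
    forcing: Optional[ForcingSeries] = None  # None → synthetic from config
    constant_supply_m3h: float = 2.4
    supply_cutoff_h: Optional[float] = None  # None → tied to the transfer dates

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "ScenarioDefinition":
        sc = config.scenario
        cohort = FishCohort(
            count=config.fish.initial_count,
            mean_weight_g=config.fish.initial_mean_weight_g,
            sd_weight_g=config.fish.initial_sd_weight_g,
        )
        fc = config.feed
        plan = FeedPlan(
            feed=fc.spec,
            ration_g_per_fish=fc.ration_g_per_fish if fc.ration_mode == "fixed" else None,
            ration_frac_bw=fc.ration_frac_bw if fc.ration_mode == "fraction_bw" else None,
        )
        return cls(
            name=sc.name,
            variant=sc.variant,
            horizon_d=sc.horizon_d,
            cohort=cohort,
            feed_plan=plan,
            constant_supply_m3h=sc.constant_supply_m3h,
            supply_cutoff_h=sc.supply_cutoff_h,
        )


@dataclass
class RunInputs:
    """Hourly model inputs retained for budget accounting."""

    temperature_C: np.ndarray
    inlet_DO_mgL: np.ndarray
    flow_Lh: np.ndarray
    source_dc_mgL: np.ndarray
    supply_m3h: np.ndarray
    sink_mgL_per_h: np.ndarray  # (n_hours, n_nodes)
    k_rear_per_h: float
    csat_mgL: np.ndarray
    geometry: RacewayGeometry
    dx_m: float


@dataclass
class DOBudget:
    """Hourly DO-budget decomposition, all components in mg/L.

    ``reaeration`` and ``respiration`` are the reaction terms accumulated
    along the raceway and divided by the through-flow; respiration is a
    consumption and therefore reported as a negative component. Under
    quasi-steady conditions outlet ≈ inlet + source + reaeration +
    respiration.
    """

    time_h: np.ndarray
    inlet: np.ndarray
    outlet: np.ndarray
    source: np.ndarray
    reaeration: np.ndarray
    respiration: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.respiration > 1e-12):
            raise DomainError("respiration component must be non-positive")
        if np.any(self.source < 0):
            raise DomainError("source component must be non-negative")


@dataclass
class ScenarioResult:
    name: str
    growth: GrowthTrajectory
    utilization_time_d: np.ndarray
    utilization_pct: np.ndarray
    biomass_kg_by_day: np.ndarray
    do_field: DOField
    budget: DOBudget
    events: list
    inputs: RunInputs
    supply_m3h: np.ndarray


def _transfer_delay_days(variant: str) -> float:
    return 0.0 if variant == "A" else 7.0


def _plan_transfers(growth: GrowthTrajectory, rule: TransferRule,
                    volume_m3: float, horizon_d: float):
    """Iteratively schedule fractional transfers from the growth forecast.

    Returns (per-day count factor, transfer events). Growth of individual
    weight is independent of stocking, so the post-transfer biomass forecast
    is the pre-transfer one scaled by the surviving count fraction.
    """
    t = growth.time_d
    n = len(t)
    factor = np.ones(n)
    events = []
    current = 1.0
    day_idx = 0
    while day_idx < n:
        biomass = growth.biomass_kg[day_idx:] * current
        event = plan_transfer(t[day_idx:], biomass, rule, volume_m3,
                              planning_time_d=float(t[day_idx]))
        if event is None:
            break
        e_idx = int(np.searchsorted(t, event.day - 1e-9))
        e_idx = min(e_idx, n - 1)
        current *= 1.0 - event.fraction
        factor[e_idx + 1:] = current  # transfer effective after that day's report
        events.append({
            "kind": "transfer",
            "day": float(t[e_idx]),
            "fraction": event.fraction,
            "predicted_crossing_day": event.predicted_crossing_day,
        })
        day_idx = e_idx + 1
    return factor, events


def run_scenario(defn: ScenarioDefinition, config: SimulationConfig) -> ScenarioResult:
    """Run one coupled scenario and return its full result set.

    Deterministic for a fixed config seed; infeasible closed-loop demands
    complete with saturation flags in the event log rather than raising.
    """
    geometry = config.geometry
    horizon_d = defn.horizon_d
    forcing = defn.forcing
    if forcing is None:
        forcing = synthetic_forcing(
            config.forcing.synthetic, horizon_d, seed=config.seed,
            start_date=config.start_date,
            pressure_atm=config.do_model.pressure_atm,
        )
    if forcing.duration_h + 1e-9 < horizon_d * 24.0:
        raise DomainError("forcing does not cover the scenario horizon")

    cohort = defn.cohort or FishCohort(count=1.0, mean_weight_g=100.0)
    feed_plan = defn.feed_plan or FeedPlan()
    params = config.fish.params

    growth = integrate_growth(cohort, forcing, feed_plan, params,
                              dt_d=config.time_step_growth_d, horizon_d=horizon_d)

    events: list = []
    n_days = len(growth.time_d)
    if defn.variant == "none" or growth.starvation_collapse:
        factor = np.ones(n_days)
        if growth.starvation_collapse:
            events.append({"kind": "starvation_collapse",
                           "day": float(growth.time_d[-1])})
    else:
        rule = TransferRule.from_config(
            config.management, delay_days=_transfer_delay_days(defn.variant))
        factor, transfer_events = _plan_transfers(
            growth, rule, geometry.volume_m3, horizon_d)
        events.extend(transfer_events)

    biomass_by_day = growth.biomass_kg * factor
    baseline = config.management.baseline_kg_m3
    utilization_pct = biomass_by_day / geometry.volume_m3 / baseline * 100.0

    # --- open-loop supply schedule -------------------------------------
    cutoff_h = defn.supply_cutoff_h
    if cutoff_h is None and defn.variant in ("A", "B1", "B2"):
        a_rule = TransferRule.from_config(config.management, delay_days=0.0)
        a_event = plan_transfer(growth.time_d, growth.biomass_kg, a_rule,
                                geometry.volume_m3)
        if a_event is not None:
            cutoff_h = a_event.day * 24.0
            if defn.variant == "B2":
                cutoff_h += 7.0 * 24.0
    schedule = None
    if defn.variant in _OPEN_LOOP_VARIANTS and config.control.mode == "open_loop":
        end_h = cutoff_h if cutoff_h is not None else horizon_d * 24.0
        if defn.variant == "none" or defn.constant_supply_m3h == 0 or end_h <= 0:
            schedule = SupplySchedule([])
        else:
            schedule = SupplySchedule([(0.0, end_h, defn.constant_supply_m3h)])
            if cutoff_h is not None and cutoff_h < horizon_d * 24.0:
                events.append({"kind": "supply_cutoff", "time_h": float(cutoff_h)})

    mode = config.control.mode
    if defn.variant in ("green", "welfare"):
        mode = defn.variant

    # --- hourly DO + control loop --------------------------------------
    dx = geometry.length_m / config.n_cells
    n_nodes = config.n_cells + 1
    x = np.linspace(0.0, geometry.length_m, n_nodes)
    rear = ReaerationParams.from_config(config.do_model)
    dt_do = config.time_step_do_h
    n_hours = int(round(horizon_d * 24.0 / dt_do))

    # hour-by-hour model inputs, known up-front (the twin's forecast)
    temp_arr = np.empty(n_hours)
    inlet_arr = np.empty(n_hours)
    flow_arr = np.empty(n_hours)
    csat_arr = np.empty(n_hours)
    sink_arr = np.empty((n_hours, n_nodes))
    biom_arr = np.empty(n_hours)
    rspec_arr = np.empty(n_hours)
    for k in range(n_hours):
        t_h = k * dt_do
        day = min(int(t_h // 24.0), n_days - 1)
        idx = forcing.index_at(t_h)
        T = float(forcing.temperature_C[idx])
        temp_arr[k] = T
        inlet_arr[k] = float(forcing.inlet_DO_mgL[idx])
        flow_arr[k] = float(forcing.flow_Lh[idx])
        csat_arr[k] = csat(T, rear)
        w = growth.mean_weight_g[day]
        count = growth.count[day] * factor[day]
        intake = feed_plan.intake_kJ(day, w)
        resp_ind = metabolic_outputs(w, T, intake, params, feed_plan.feed)
        rspec_arr[k] = resp_ind.respiration_mgO2_per_h / (w / 1000.0)
        biom_arr[k] = count * w / 1000.0
        sink_arr[k] = (rspec_arr[k] * (biom_arr[k] / geometry.length_m)
                       / (geometry.cross_section_m2 * 1000.0))

    srcdc_arr = np.empty(n_hours)
    supply_arr = np.empty(n_hours)
    n_lookahead = int(np.ceil(
        (config.control.control_interval_h
         + geometry.volume_m3 / (float(np.min(flow_arr)) / 1000.0)) / dt_do)) + 1

    C = _initial_profile(x, forcing, growth, factor, feed_plan, params, config,
                         geometry, rear, mode, schedule, defn)
    initial_state = C.copy()
    states = []
    times = [0.0]
    valve = 0.0
    for k in range(n_hours):
        t_h = k * dt_do
        T = temp_arr[k]
        c_river = inlet_arr[k]
        Q = flow_arr[k]
        u = (Q / 1000.0) / geometry.cross_section_m2
        sink = sink_arr[k]

        if mode == "open_loop":
            supply = scheduled_supply(schedule, t_h) if schedule else 0.0
        elif mode in ("green", "welfare"):
            profile = BiomassProfile(
                x, np.full(n_nodes, biom_arr[k] / geometry.length_m),
                biom_arr[k], rspec_arr[k])
            forecast = [
                ForecastSegment(dt_do, temp_arr[j], inlet_arr[j], flow_arr[j],
                                sink_arr[j])
                for j in range(k, min(k + n_lookahead, n_hours))
            ]
            state = RacewayControlState(C, T, c_river, Q, profile, forecast)
            fn = green_supply if mode == "green" else welfare_supply
            decision: ControlDecision = fn(
                state, geometry, rear, config.control,
                gas_density_kg_m3=config.do_model.gas_density_kg_m3,
                efficiency=config.do_model.source_efficiency,
                dx_m=dx,
            )
            supply = decision.supply_m3h
            if decision.saturated:
                events.append({"kind": "saturation", "time_h": float(t_h),
                               "supply_m3h": supply})
        elif mode == "feedback":
            measured = float(C[-1])
            valve = feedback_step(measured, config.control.setpoint_mgL, valve,
                                  config.control.gain,
                                  config.control.max_supply_m3h)
            supply = valve
        else:  # pragma: no cover - schema forbids
            raise RacewayError(f"unknown control mode {mode!r}")

        src = OxygenSource(supply, config.do_model.gas_density_kg_m3,
                           config.do_model.source_efficiency)
        dc = source_increment(src, Q)
        dt_sub = config.do_model.cfl_safety * dx / u
        C, _, _, budget = advance_interval(
            C, c_river + dc, dt_do, dt_sub, u, dx, rear.k_rear_per_h,
            csat_arr[k], sink)
        if budget["clipped"] > 0:
            events.append({"kind": "anoxia", "time_h": float(t_h + dt_do),
                           "clipped_mgL": budget["clipped"]})

        srcdc_arr[k] = dc
        supply_arr[k] = supply
        times.append(t_h + dt_do)
        states.append(C.copy())

    field = DOField(
        x_m=x, time_h=np.asarray(times),
        C=np.column_stack([initial_state] + states),
    )
    inputs = RunInputs(temp_arr, inlet_arr, flow_arr, srcdc_arr, supply_arr,
                       sink_arr, rear.k_rear_per_h, csat_arr, geometry, dx)
    budget = budget_decomposition(field, inputs)
    return ScenarioResult(
        name=defn.name, growth=growth,
        utilization_time_d=growth.time_d, utilization_pct=utilization_pct,
        biomass_kg_by_day=biomass_by_day,
        do_field=field, budget=budget, events=events, inputs=inputs,
        supply_m3h=supply_arr,
    )


def _initial_profile(x, forcing, growth, factor, feed_plan, params, config,
                     geometry, rear, mode, schedule, defn) -> np.ndarray:
    """Policy-consistent steady DO profile for t = 0.

    A scenario starts on an already-operating raceway, so the initial water
    column carries the drawdown (and any supply enrichment) of the
    steady regime under the first hour's forcing — not pristine river water.
    The profile is the solver's own converged steady state (relaxed over
    five residence times of constant hour-0 forcing), with the supply chosen
    by the same rule the policy applies at t = 0.
    """
    T = float(forcing.temperature_C[0])
    c_river = float(forcing.inlet_DO_mgL[0])
    Q = float(forcing.flow_Lh[0])
    w = growth.mean_weight_g[0]
    count = growth.count[0] * factor[0]
    intake = feed_plan.intake_kJ(0, w)
    resp_ind = metabolic_outputs(w, T, intake, params, feed_plan.feed)
    r_spec = resp_ind.respiration_mgO2_per_h / (w / 1000.0)
    m_total = count * w / 1000.0
    profile = BiomassProfile(
        x, np.full(len(x), m_total / geometry.length_m), m_total, r_spec)

    u = (Q / 1000.0) / geometry.cross_section_m2
    dx = x[1] - x[0]
    sink = r_spec * profile.density_kg_per_m / (geometry.cross_section_m2 * 1000.0)
    relax_h = 5.0 * geometry.length_m / u
    dt_sub = config.do_model.cfl_safety * dx / u

    def steady(supply: float) -> np.ndarray:
        src = OxygenSource(supply, config.do_model.gas_density_kg_m3,
                           config.do_model.source_efficiency)
        c_in = c_river + source_increment(src, Q)
        C_end, _, _, _ = advance_interval(
            np.full(len(x), c_in), c_in, relax_h, dt_sub, u, dx,
            rear.k_rear_per_h, csat(T, rear), sink)
        return C_end

    ctl = config.control
    if mode == "open_loop":
        supply = scheduled_supply(schedule, 0.0) if schedule else 0.0
    elif mode == "welfare":
        supply = _bisect_supply(lambda s: float(steady(s).min()) - ctl.threshold_mgL,
                                ctl.max_supply_m3h, ctl.supply_tol_m3h)
    elif mode == "green":
        supply = _bisect_supply(lambda s: float(steady(s)[-1]) - c_river,
                                ctl.max_supply_m3h, ctl.supply_tol_m3h)
    else:  # feedback: valve starts closed
        supply = 0.0
    return np.clip(steady(supply), 0.0, None)


def _bisect_supply(objective, max_supply: float, tol: float) -> float:
    lo, hi = 0.0, max_supply
    if objective(lo) >= 0.0:
        return 0.0
    if objective(hi) < 0.0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if objective(mid) >= 0.0:
            hi = mid
        else:
            lo = mid
    return hi


def budget_decomposition(field: DOField, inputs: RunInputs) -> DOBudget:
    """Decompose the DO balance per reported step, all in mg/L.

    Reaction terms are integrated along the raceway from the end-of-step
    profile and divided by the through-flow, so under quasi-steady
    conditions the identity outlet = inlet + source + reaeration +
    respiration holds to within the transient storage term.
    """
    n = len(inputs.temperature_C)
    u = (inputs.flow_Lh / 1000.0) / inputs.geometry.cross_section_m2  # m/h
    C_end = field.C[:, 1:n + 1]
    rear = (inputs.k_rear_per_h
            * (inputs.csat_mgL[None, :] - C_end[1:, :]).sum(axis=0)
            * inputs.dx_m / u)
    resp = -(inputs.sink_mgL_per_h[:, 1:].sum(axis=1) * inputs.dx_m / u)
    return DOBudget(
        time_h=field.time_h[1:n + 1],
        inlet=inputs.inlet_DO_mgL.copy(),
        outlet=C_end[-1, :].copy(),
        source=inputs.source_dc_mgL.copy(),
        reaeration=rear,
        respiration=resp,
    )


def export_scenario(result: ScenarioResult, directory, force: bool = False) -> list[str]:
    """Write the scenario CSVs (+ JSON-lines event log) into a directory.

    Files: ``<name>_utilization.csv`` (time,utilization_pct,scenario),
    ``<name>_do_field.csv`` (x_m,time,DO_mgL), ``<name>_budget.csv``
    (time,inlet,outlet,source,reaeration,respiration) and
    ``<name>_events.jsonl``. Refuses to overwrite existing files unless
    ``force`` is set.
    """
    ensure_writable_dir(directory)
    name = result.name
    paths = {
        "utilization": os.path.join(directory, f"{name}_utilization.csv"),
        "do_field": os.path.join(directory, f"{name}_do_field.csv"),
        "budget": os.path.join(directory, f"{name}_budget.csv"),
        "events": os.path.join(directory, f"{name}_events.jsonl"),
    }
    if not force:
        existing = [p for p in paths.values() if os.path.exists(p)]
        if existing:
            raise RacewayError(
                "refusing to overwrite existing export(s): "
                + ", ".join(existing) + " (use force=True)"
            )
    pd.DataFrame({
        "time": result.utilization_time_d,
        "utilization_pct": result.utilization_pct,
        "scenario": result.name,
    }).to_csv(paths["utilization"], index=False, float_format=_FLOAT_FMT)
    write_field_csv(result.do_field, paths["do_field"])
    b = result.budget
    pd.DataFrame({
        "time": b.time_h, "inlet": b.inlet, "outlet": b.outlet,
        "source": b.source, "reaeration": b.reaeration,
        "respiration": b.respiration,
    }).to_csv(paths["budget"], index=False, float_format=_FLOAT_FMT)
    with open(paths["events"], "w", encoding="utf-8") as fh:
        for ev in result.events:
            fh.write(json.dumps(ev, sort_keys=True) + "\n")
    return list(paths.values())
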