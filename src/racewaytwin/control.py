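"""Oxygen-supply control policies.

Open-loop policies follow a fixed schedule regardless of the water state.
The two closed-loop policies invert the DO transport model by bisection on
the supply rate against a forward prediction over one control interval:

* **Green** — the smallest supply for which the predicted outlet DO equals
  the inlet DO, so the water returned to the stream carries the oxygen it
  arrived with (supply nearly coincident with fish demand).
* **Welfare** — the smallest supply for which the predicted minimum DO over
  the whole raceway stays at or above a welfare threshold (default
  9.5 mg/L); zero whenever the unforced minimum already satisfies it.

A proportional error-feedback valve model is provided for the sensor-driven
variant: valve ← valve + gain × (setpoint − measured), clamped to the valve
range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ControlConfig, RacewayGeometry, ScheduleSegment
from .do_transport import (
    BiomassProfile,
    OxygenSource,
    ReaerationParams,
    advance_interval,
    csat,
    source_increment,
)
from .errors import DomainError

__all__ = [
    "SupplySchedule",
    "ControlDecision",
    "ForecastSegment",
    "RacewayControlState",
    "scheduled_supply",
    "green_supply",
    "welfare_supply",
    "feedback_step",
]


@dataclass
class SupplySchedule:
    """Piecewise-constant open-loop supply: (start_h, end_h, m³/h) segments."""

    segments: list

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s[0] if isinstance(s, tuple) else s.start_h)
        norm = []
        prev_end = -np.inf
        for s in segs:
            start, end, supply = (
                (s.start_h, s.end_h, s.supply_m3h) if isinstance(s, ScheduleSegment)
                else s
            )
            if end <= start:
                raise DomainError("schedule segment end must exceed start")
            if supply < 0:
                raise DomainError("scheduled supply must be non-negative")
            if start < prev_end:
                raise DomainError("schedule segments must not overlap")
            prev_end = end
            norm.append((float(start), float(end), float(supply)))
        self.segments = norm


def scheduled_supply(schedule: SupplySchedule, t_h: float) -> float:
    """Supply of the segment containing t, else 0."""
    for start, end, supply in schedule.segments:
        if start <= t_h < end:
            return supply
    return 0.0


@dataclass
class ForecastSegment:
    """One piecewise-constant stretch of forecast forcing."""

    duration_h: float
    temperature_C: float
    inlet_DO_mgL: float
    flow_Lh: float
    sink_mgL_per_h: Optional[np.ndarray] = None  # None → use the state's biomass


@dataclass
class RacewayControlState:
    """Snapshot the closed-loop controllers predict from.

    ``forecast`` optionally carries the forthcoming forcing (the twin's
    model-based prediction); without it the current forcing is held constant
    over the horizon.
    """

    C_profile: np.ndarray           # current DO along x, mg/L
    temperature_C: float
    inlet_DO_mgL: float             # river DO before the point source
    flow_Lh: float
    biomass: BiomassProfile
    forecast: Optional[list] = None  # list[ForecastSegment]


@dataclass
class ControlDecision:
    supply_m3h: float
    saturated: bool = False
    predicted_min_mgL: Optional[float] = None
    predicted_outlet_mgL: Optional[float] = None


def _segments(state: RacewayControlState, geometry: RacewayGeometry,
              horizon_h: float) -> list:
    base_sink = (
        state.biomass.specific_respiration_mgO2_per_kg_h
        * state.biomass.density_kg_per_m
        / (geometry.cross_section_m2 * 1000.0)
    )
    if not state.forecast:
        return [ForecastSegment(horizon_h, state.temperature_C,
                                state.inlet_DO_mgL, state.flow_Lh, base_sink)]
    segs = []
    remaining = horizon_h
    for seg in state.forecast:
        if remaining <= 1e-12:
            break
        d = min(seg.duration_h, remaining)
        sink = seg.sink_mgL_per_h if seg.sink_mgL_per_h is not None else base_sink
        segs.append(ForecastSegment(d, seg.temperature_C, seg.inlet_DO_mgL,
                                    seg.flow_Lh, sink))
        remaining -= d
    if remaining > 1e-12:  # extend the last known conditions
        last = segs[-1]
        segs.append(ForecastSegment(remaining, last.temperature_C,
                                    last.inlet_DO_mgL, last.flow_Lh,
                                    last.sink_mgL_per_h))
    return segs


def _predict(state: RacewayControlState, supply_m3h: float,
             geometry: RacewayGeometry, params: ReaerationParams,
             cfg: ControlConfig, gas_density: float, efficiency: float,
             dx_m: float, dt_h: float, horizon_h: float):
    """Forward-run the solver over the horizon at a trial supply."""
    src = OxygenSource(supply_m3h, gas_density, efficiency)
    C = state.C_profile
    min_c = np.inf
    for seg in _segments(state, geometry, horizon_h):
        c_in = seg.inlet_DO_mgL + source_increment(src, seg.flow_Lh)
        u = (seg.flow_Lh / 1000.0) / geometry.cross_section_m2
        C, m, _, _ = advance_interval(
            C, c_in, seg.duration_h, dt_h, u, dx_m,
            params.k_rear_per_h, csat(seg.temperature_C, params),
            seg.sink_mgL_per_h, track_budget=False,
        )
        min_c = min(min_c, m)
    return C, min_c, float(C[-1])


def _invert_supply(objective, cfg: ControlConfig) -> tuple[float, bool]:
    """Smallest supply in [0, max] with objective(supply) ≥ 0, by bisection.

    The objective is monotone non-decreasing in supply (more oxygen in, more
    everywhere downstream). Returns (supply, saturated).
    """
    lo, hi = 0.0, cfg.max_supply_m3h
    if objective(lo) >= 0.0:
        return 0.0, False
    if objective(hi) < 0.0:
        return hi, True
    while hi - lo > cfg.supply_tol_m3h:
        mid = 0.5 * (lo + hi)
        if objective(mid) >= 0.0:
            hi = mid
        else:
            lo = mid
    return hi, False


def green_supply(
    state: RacewayControlState,
    geometry: RacewayGeometry,
    params: ReaerationParams,
    cfg: ControlConfig,
    gas_density_kg_m3: float = 1.429,
    efficiency: float = 0.9,
    dx_m: float = 2.0,
    dt_h: Optional[float] = None,
    horizon_h: Optional[float] = None,
) -> ControlDecision:
    """Supply that returns the inlet DO concentration at the outlet.

    Zero when the unforced outlet already meets or exceeds the inlet (e.g.
    no fish, or strong reaeration); clamped with a saturation flag when the
    demand exceeds the valve capacity.
    """
    horizon_h, dt_h = _default_steps(state, geometry, cfg, dx_m, dt_h, horizon_h)

    def objective(s: float) -> float:
        _, _, outlet = _predict(state, s, geometry, params, cfg,
                                gas_density_kg_m3, efficiency, dx_m, dt_h, horizon_h)
        return outlet - state.inlet_DO_mgL

    supply, saturated = _invert_supply(objective, cfg)
    _, min_c, outlet = _predict(state, supply, geometry, params, cfg,
                                gas_density_kg_m3, efficiency, dx_m, dt_h, horizon_h)
    return ControlDecision(supply, saturated, min_c, outlet)


def welfare_supply(
    state: RacewayControlState,
    geometry: RacewayGeometry,
    params: ReaerationParams,
    cfg: ControlConfig,
    threshold_mgL: Optional[float] = None,
    gas_density_kg_m3: float = 1.429,
    efficiency: float = 0.9,
    dx_m: float = 2.0,
    dt_h: Optional[float] = None,
    horizon_h: Optional[float] = None,
) -> ControlDecision:
    """Supply that keeps the predicted minimum DO at or above a threshold.

    Exactly zero when the unforced minimum already satisfies the floor;
    clamped with a saturation flag when the floor is unattainable.
    """
    threshold = cfg.threshold_mgL if threshold_mgL is None else threshold_mgL
    horizon_h, dt_h = _default_steps(state, geometry, cfg, dx_m, dt_h, horizon_h)

    def objective(s: float) -> float:
        _, min_c, _ = _predict(state, s, geometry, params, cfg,
                               gas_density_kg_m3, efficiency, dx_m, dt_h, horizon_h)
        return min_c - threshold

    supply, saturated = _invert_supply(objective, cfg)
    _, min_c, outlet = _predict(state, supply, geometry, params, cfg,
                                gas_density_kg_m3, efficiency, dx_m, dt_h, horizon_h)
    return ControlDecision(supply, saturated, min_c, outlet)


def feedback_step(
    measured_DO_mgL: float,
    setpoint_mgL: float,
    current_valve_m3h: float,
    gain: float,
    max_supply_m3h: float,
) -> float:
    """Proportional valve update: valve + gain × (setpoint − measured), clamped."""
    if gain < 0:
        raise DomainError("gain must be non-negative")
    valve = current_valve_m3h + gain * (setpoint_mgL - measured_DO_mgL)
    return float(np.clip(valve, 0.0, max_supply_m3h))


def _default_steps(state, geometry, cfg, dx_m, dt_h, horizon_h):
    u = (state.flow_Lh / 1000.0) / geometry.cross_section_m2
    if horizon_h is None:
        # one control interval plus one residence time, so the decision sees
        # the full transit of every parcel admitted under it
        horizon_h = cfg.control_interval_h + geometry.length_m / u
    if dt_h is None:
        dt_h = 0.9 * dx_m / u
    return horizon_h, dt_h
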