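"""Stocking bookkeeping, utilization factor and intervention rules.

The utilization factor is current biomass density divided by a baseline
transfer density (default 20 kg/m³, following flow-through trout practice).
When a growth forecast predicts full utilization, a fixed fraction of the
stock (default one third) is transferred out one day beforehand; a delayed
variant postpones the same transfer by a configured number of days.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .config import FishCohort, ManagementConfig, RacewayGeometry
from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "StockingState",
    "TransferRule",
    "TransferEvent",
    "InterventionProposal",
    "utilization_factor",
    "stocking_state",
    "plan_transfer",
    "apply_transfer",
    "propose_interventions",
    "daily_feed_quantity",
]

# irreversible actions first when several rules fire the same day
_KIND_PRIORITY = ("harvest", "transfer", "change_feed", "set_feed_quantity",
                  "set_oxygen_supply")

_KIND_TRIGGERS = {
    "harvest": "fish_weight",
    "transfer": "biomass_density",
    "change_feed": "fish_weight",
    "set_feed_quantity": "fish_weight",
    "set_oxygen_supply": "DO_concentration",
}


def utilization_factor(density_kg_m3: float, baseline_kg_m3: float) -> float:
    """Biomass density over the baseline transfer density (1.0 = 100%)."""
    if baseline_kg_m3 <= 0:
        raise DomainError("baseline density must be strictly positive")
    if density_kg_m3 < 0:
        raise DomainError("density must be non-negative")
    return density_kg_m3 / baseline_kg_m3


@dataclass
class TransferRule:
    baseline_kg_m3: float = 20.0
    fraction: float = 1.0 / 3.0
    lead_days: float = 1.0
    delay_days: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_kg_m3 <= 0:
            raise DomainError("baseline density must be strictly positive")
        if not (0 < self.fraction <= 1):
            raise DomainError("transfer fraction must lie in (0, 1]")
        if self.lead_days < 0 or self.delay_days < 0:
            raise DomainError("lead and delay days must be non-negative")

    @classmethod
    def from_config(cls, cfg: ManagementConfig, delay_days: Optional[float] = None
                    ) -> "TransferRule":
        return cls(cfg.baseline_kg_m3, cfg.transfer_fraction, cfg.lead_days,
                   cfg.delay_days if delay_days is None else delay_days)


@dataclass
class TransferEvent:
    day: float
    fraction: float
    predicted_crossing_day: float
    immediate: bool = False


@dataclass
class StockingState:
    """Cohort plus derived density and utilization for one raceway."""

    cohort: FishCohort
    volume_m3: float
    baseline_kg_m3: float

    @property
    def biomass_kg(self) -> float:
        return self.cohort.biomass_kg

    @property
    def density_kg_m3(self) -> float:
        return self.biomass_kg / self.volume_m3

    @property
    def utilization(self) -> float:
        return utilization_factor(self.density_kg_m3, self.baseline_kg_m3)


def stocking_state(cohort: FishCohort, geometry: RacewayGeometry,
                   baseline_kg_m3: float = 20.0) -> StockingState:
    return StockingState(cohort, geometry.volume_m3, baseline_kg_m3)


def plan_transfer(
    forecast_time_d: Sequence[float],
    forecast_biomass_kg: Sequence[float],
    rule: TransferRule,
    volume_m3: float,
    planning_time_d: float = 0.0,
) -> Optional[TransferEvent]:
    """Schedule a fractional transfer from a biomass forecast.

    The event lands ``lead_days`` before the first forecast day on which the
    utilization factor would reach 100%, plus any configured delay. Returns
    None when no crossing occurs within the forecast horizon. A crossing
    already in the past at planning time produces an immediate event at the
    next step with a warning.
    """
    t = np.asarray(forecast_time_d, dtype=float)
    b = np.asarray(forecast_biomass_kg, dtype=float)
    if len(t) != len(b) or len(t) == 0:
        raise DomainError("forecast arrays must be non-empty and equal length")
    util = b / (volume_m3 * rule.baseline_kg_m3)
    crossing = np.nonzero(util >= 1.0)[0]
    if len(crossing) == 0:
        return None
    cross_day = float(t[crossing[0]])
    event_day = cross_day - rule.lead_days + rule.delay_days
    if event_day < planning_time_d:
        warnings.warn(
            f"utilization crossing at day {cross_day:g} is already within "
            f"lead time at planning day {planning_time_d:g}; scheduling an "
            "immediate transfer",
            stacklevel=2,
        )
        return TransferEvent(planning_time_d, rule.fraction, cross_day,
                             immediate=True)
    return TransferEvent(event_day, rule.fraction, cross_day)


def apply_transfer(state: StockingState, fraction: float) -> StockingState:
    """Remove a fraction of individuals; per-fish weights are unchanged."""
    if not (0 <= fraction <= 1):
        raise DomainError("transfer fraction must lie in [0, 1]")
    c = state.cohort
    new_cohort = FishCohort(
        count=c.count * (1.0 - fraction),
        mean_weight_g=c.mean_weight_g,
        sd_weight_g=c.sd_weight_g,
        deaths_cum=c.deaths_cum,
    )
    return replace(state, cohort=new_cohort)


@dataclass
class InterventionProposal:
    kind: str
    trigger_variable: str
    due_day: float
    detail: str = ""

    def __post_init__(self) -> None:
        if _KIND_TRIGGERS.get(self.kind) != self.trigger_variable:
            raise DomainError(
                f"kind {self.kind!r} must be triggered by "
                f"{_KIND_TRIGGERS.get(self.kind)!r}, not {self.trigger_variable!r}"
            )


def propose_interventions(
    state: StockingState,
    config: ManagementConfig,
    day: float = 0.0,
    min_do_mgL: Optional[float] = None,
    do_setpoint_mgL: Optional[float] = None,
    forecast_time_d: Optional[Sequence[float]] = None,
    forecast_biomass_kg: Optional[Sequence[float]] = None,
) -> list[InterventionProposal]:
    """Evaluate the intervention rules against the current state.

    Rules whose thresholds are not configured are skipped with a logged
    warning; at most one proposal of each kind is returned per call (the
    caller enforces per-cadence deduplication across calls). Proposals are
    ordered with irreversible actions first.
    """
    proposals: list[InterventionProposal] = []
    w = state.cohort.mean_weight_g

    if config.harvest_weight_g is None:
        logger.warning("harvest rule skipped: harvest_weight_g not configured")
    elif w >= config.harvest_weight_g:
        proposals.append(InterventionProposal(
            "harvest", "fish_weight", day,
            f"mean weight {w:.0f} g ≥ harvest weight {config.harvest_weight_g:.0f} g"))

    if forecast_time_d is not None and forecast_biomass_kg is not None:
        rule = TransferRule.from_config(config)
        event = plan_transfer(forecast_time_d, forecast_biomass_kg, rule,
                              state.volume_m3, planning_time_d=day)
        if event is not None:
            proposals.append(InterventionProposal(
                "transfer", "biomass_density", event.day,
                f"transfer {rule.fraction:.3f} of biomass "
                f"(predicted 100% utilization on day {event.predicted_crossing_day:g})"))

    row = _feed_table_row(config, w)
    if row is None:
        logger.warning("feed rules skipped: weight %.0f g outside the feed table", w)
    else:
        boundary_idx = config.feed_table.index(row)
        if boundary_idx > 0 and w > config.feed_table[boundary_idx - 1].max_weight_g:
            proposals.append(InterventionProposal(
                "change_feed", "fish_weight", day,
                f"weight class up to {row.max_weight_g:.0f} g"))
        proposals.append(InterventionProposal(
            "set_feed_quantity", "fish_weight", day + 1,
            f"ration {row.ration_frac_bw * 100:.2f}% BW"))

    if min_do_mgL is not None and do_setpoint_mgL is not None:
        if min_do_mgL < do_setpoint_mgL:
            proposals.append(InterventionProposal(
                "set_oxygen_supply", "DO_concentration", day + 1.0 / 24.0,
                f"min DO {min_do_mgL:.2f} mg/L below setpoint "
                f"{do_setpoint_mgL:.2f} mg/L"))

    proposals.sort(key=lambda p: _KIND_PRIORITY.index(p.kind))
    return proposals


def _feed_table_row(config: ManagementConfig, weight_g: float):
    for row in config.feed_table:
        if weight_g <= row.max_weight_g:
            return row
    return None


def daily_feed_quantity(cohort: FishCohort, T_C: float,
                        config: ManagementConfig) -> float:
    """Next-day feed quantity, kg: count × weight × tabulated %BW ration.

    Feeding stops below the configured minimum temperature.
    """
    row = _feed_table_row(config, cohort.mean_weight_g)
    if row is None:
        raise DomainError(
            f"no feed-table class covers weight {cohort.mean_weight_g:.0f} g "
            f"(largest class ends at {config.feed_table[-1].max_weight_g:.0f} g)"
        )
    if T_C < config.min_feeding_temp_C:
        return 0.0
    return cohort.count * cohort.mean_weight_g * row.ration_frac_bw / 1000.0
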