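"""Configuration schema and core domain containers.

Unit conventions are fixed at the package boundary and never converted inside
numerics: temperature °C, dissolved oxygen mg/L, water flow L/h, lengths m,
individual weight g, biomass kg, energy kJ. Time is fractional days from the
simulation start date for growth/management, fractional hours for the DO
model; calendar dates map through ``SimulationConfig.start_date``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from pydantic import ValidationError as _PydanticValidationError

from .errors import ConfigurationError, DomainError

_REL_TOL = 1e-9


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class RacewayGeometry(_StrictModel):
    """Physical domain of one flow-through raceway.

    The streamwise coordinate x runs from 0 at the inlet to ``length_m`` at
    the outlet. Cross-section A = width × depth carries the advective
    velocity u = Q/A. Depth is site-specific and has no universal default;
    it must always be supplied.
    """

    length_m: float = 200.0
    width_m: float = 8.0
    depth_m: float
    cross_section_m2: Optional[float] = None
    volume_m3: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "RacewayGeometry":
        for name in ("length_m", "width_m", "depth_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        a = self.width_m * self.depth_m
        v = self.length_m * a
        if self.cross_section_m2 is None:
            object.__setattr__(self, "cross_section_m2", a)
        elif abs(self.cross_section_m2 - a) > _REL_TOL * a:
            raise ValueError("cross_section_m2 inconsistent with width × depth")
        if self.volume_m3 is None:
            object.__setattr__(self, "volume_m3", v)
        elif abs(self.volume_m3 - v) > _REL_TOL * v:
            raise ValueError("volume_m3 inconsistent with length × width × depth")
        return self


@dataclass
class ForcingSeries:
    """Time-indexed boundary forcing: temperature, inlet DO and flow.

    ``time_h`` is in hours from the series start, strictly increasing.
    ``start`` optionally anchors t=0 to a calendar instant.
    """

    time_h: np.ndarray
    temperature_C: np.ndarray
    inlet_DO_mgL: np.ndarray
    flow_Lh: np.ndarray
    start: Optional[_dt.datetime] = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.inlet_DO_mgL = np.asarray(self.inlet_DO_mgL, dtype=float)
        self.flow_Lh = np.asarray(self.flow_Lh, dtype=float)
        n = len(self.time_h)
        if not (len(self.temperature_C) == len(self.inlet_DO_mgL) == len(self.flow_Lh) == n):
            raise DomainError("forcing arrays must have equal length")
        if n == 0:
            raise DomainError("forcing series must not be empty")
        if np.any(np.diff(self.time_h) <= 0):
            raise DomainError("forcing timestamps must be strictly increasing")
        if np.any((self.temperature_C < -1.0) | (self.temperature_C > 40.0)):
            raise DomainError("temperature outside [-1, 40] °C")
        if np.any(self.inlet_DO_mgL < 0):
            raise DomainError("inlet DO must be non-negative")
        if np.any(self.flow_Lh <= 0):
            raise DomainError("flow must be strictly positive")

    def __len__(self) -> int:
        return len(self.time_h)

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    def temperature_at(self, t_h: float) -> float:
        return float(np.interp(t_h, self.time_h, self.temperature_C))

    def inlet_do_at(self, t_h: float) -> float:
        return float(np.interp(t_h, self.time_h, self.inlet_DO_mgL))

    def flow_at(self, t_h: float) -> float:
        return float(np.interp(t_h, self.time_h, self.flow_Lh))

    def index_at(self, t_h: float) -> int:
        """Index of the forcing record in force at time ``t_h`` (zero-order hold)."""
        i = int(np.searchsorted(self.time_h, t_h, side="right")) - 1
        return max(0, min(i, len(self) - 1))


@dataclass
class FishCohort:
    """Population state of one raceway: count, weight distribution, deaths."""

    count: float
    mean_weight_g: float
    sd_weight_g: float = 0.0
    deaths_cum: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise DomainError("count must be non-negative")
        if self.mean_weight_g <= 0:
            raise DomainError("mean weight must be strictly positive")
        if self.sd_weight_g < 0 or self.deaths_cum < 0:
            raise DomainError("sd and cumulative deaths must be non-negative")

    @property
    def biomass_kg(self) -> float:
        return self.count * self.mean_weight_g / 1000.0


class FeedSpec(_StrictModel):
    """Proximate feed composition with gross-energy coefficients (kJ/g)."""

    protein_frac: float = 0.45
    lipid_frac: float = 0.25
    carb_frac: float = 0.15
    gross_energy_coeffs: tuple[float, float, float] = (23.6, 39.5, 17.2)

    @model_validator(mode="after")
    def _check(self) -> "FeedSpec":
        fracs = (self.protein_frac, self.lipid_frac, self.carb_frac)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("feed fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("feed fractions must sum to at most 1")
        if any(c <= 0 for c in self.gross_energy_coeffs):
            raise ValueError("gross-energy coefficients must be strictly positive")
        return self


class BioenergeticParams(_StrictModel):
    """Parameters of the net-energy-budget growth model for rainbow trout.

    Defaults are a generic trout parameterisation chosen to satisfy sanity
    envelopes (fingerling to commercial weight in one growing season at
    8–16 °C, routine metabolism of order 300 mg O2 kg⁻¹ h⁻¹); they are not a
    site calibration and every value is config-overridable.
    """

    anab_coeff: float = 1.9          # kJ g^-m d^-1, scale of maximum ingestion
    anab_exponent: float = 2.0 / 3.0  # m, ingestion allometry
    catab_coeff: float = 0.01        # d^-1, catabolic weight-loss rate at 0 °C
    catab_exponent: float = 1.0      # n, catabolism allometry
    catab_temp_coeff: float = 0.05   # °C^-1, exponential temperature factor
    anab_temp_optimum: float = 14.0  # °C
    anab_temp_max: float = 24.0      # °C, ingestion shuts down here
    assimilation_eff: float = 0.7
    fish_energy_density: float = 6.0  # kJ per g wet weight
    oxycal_coeff: float = 1000.0 / 13.6  # mg O2 per kJ metabolised
    sda_frac: float = 0.15           # metabolic cost fraction of intake energy
    protein_catab_frac: float = 0.3
    tan_per_protein: float = 0.092   # g TAN per g protein catabolised
    co2_per_O2: float = 44.0 / 32.0  # g CO2 per g O2 respired (RQ = 1)

    @model_validator(mode="after")
    def _check(self) -> "BioenergeticParams":
        for name in ("anab_exponent", "catab_exponent"):
            v = getattr(self, name)
            if not (0 < v <= 1.5):
                raise ValueError(f"{name} must lie in (0, 1.5]")
        for name in ("assimilation_eff", "sda_frac", "protein_catab_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("anab_coeff", "catab_coeff", "catab_temp_coeff",
                     "fish_energy_density", "oxycal_coeff", "tan_per_protein",
                     "co2_per_O2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.anab_temp_optimum >= self.anab_temp_max:
            raise ValueError("anab_temp_optimum must be below anab_temp_max")
        return self


class DOModelConfig(_StrictModel):
    """Numerical and physical settings of the 1-D DO transport model."""

    k_rear_per_h: float = 0.1
    csat_formula: Literal["benson-krause"] = "benson-krause"
    pressure_atm: float = 1.0
    gas_density_kg_m3: float = 1.429   # gasified O2 at standard conditions
    source_efficiency: float = 0.9     # liquid→gas transfer efficiency
    dx_m: float = 2.0
    cfl_safety: float = 0.9

    @model_validator(mode="after")
    def _check(self) -> "DOModelConfig":
        if self.k_rear_per_h < 0:
            raise ValueError("k_rear_per_h must be non-negative")
        if not (0 <= self.source_efficiency <= 1):
            raise ValueError("source_efficiency must lie in [0, 1]")
        if self.dx_m <= 0 or self.pressure_atm <= 0 or self.gas_density_kg_m3 <= 0:
            raise ValueError("dx_m, pressure_atm, gas_density_kg_m3 must be positive")
        if not (0 < self.cfl_safety <= 1):
            raise ValueError("cfl_safety must lie in (0, 1]")
        return self


class ScheduleSegment(_StrictModel):
    start_h: float
    end_h: float
    supply_m3h: float

    @model_validator(mode="after")
    def _check(self) -> "ScheduleSegment":
        if self.end_h <= self.start_h:
            raise ValueError("segment end must exceed start")
        if self.supply_m3h < 0:
            raise ValueError("supply must be non-negative")
        return self


class ControlConfig(_StrictModel):
    """Oxygen-supply policy block."""

    mode: Literal["open_loop", "green", "welfare", "feedback"] = "open_loop"
    threshold_mgL: float = 9.5       # welfare floor
    setpoint_mgL: float = 9.0        # feedback target
    max_supply_m3h: float = 5.0
    gain: float = 0.5                # m³/h per mg/L of error
    control_interval_h: float = 1.0
    supply_tol_m3h: float = 1e-3
    outlet_tol_mgL: float = 0.05
    schedule: list[ScheduleSegment] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "ControlConfig":
        if self.threshold_mgL <= 0 or self.max_supply_m3h < 0 or self.gain < 0:
            raise ValueError("threshold > 0, max_supply ≥ 0, gain ≥ 0 required")
        if self.control_interval_h <= 0:
            raise ValueError("control_interval_h must be positive")
        prev_end = -np.inf
        for seg in sorted(self.schedule, key=lambda s: s.start_h):
            if seg.start_h < prev_end:
                raise ValueError("schedule segments must not overlap")
            prev_end = seg.end_h
        return self


class FeedTableRow(_StrictModel):
    max_weight_g: float
    ration_frac_bw: float  # daily ration as fraction of body weight


class ManagementConfig(_StrictModel):
    """Stocking-density and intervention-rule block.

    The 20 kg/m³ baseline density and the one-third transfer fraction follow
    common flow-through trout practice (FAO-style recommendations); the feed
    table is a three-class illustrative stub.
    """

    baseline_kg_m3: float = 20.0
    transfer_fraction: float = 1.0 / 3.0
    lead_days: float = 1.0
    delay_days: float = 0.0
    harvest_weight_g: Optional[float] = 400.0
    min_feeding_temp_C: float = 2.0
    feed_table: list[FeedTableRow] = Field(
        default_factory=lambda: [
            FeedTableRow(max_weight_g=50.0, ration_frac_bw=0.025),
            FeedTableRow(max_weight_g=200.0, ration_frac_bw=0.018),
            FeedTableRow(max_weight_g=600.0, ration_frac_bw=0.012),
        ]
    )

    @model_validator(mode="after")
    def _check(self) -> "ManagementConfig":
        if self.baseline_kg_m3 <= 0:
            raise ValueError("baseline_kg_m3 must be strictly positive")
        if not (0 < self.transfer_fraction <= 1):
            raise ValueError("transfer_fraction must lie in (0, 1]")
        if self.lead_days < 0 or self.delay_days < 0:
            raise ValueError("lead_days and delay_days must be non-negative")
        return self


class SyntheticForcingConfig(_StrictModel):
    """Parameters of the synthetic forcing generator (see forcing module)."""

    mean_temperature_C: float = 13.0
    seasonal_amplitude_C: float = 6.0
    diurnal_amplitude_C: float = 0.8
    inlet_do_mean_mgL: Optional[float] = None  # None → track saturation
    inlet_do_saturation: float = 1.0
    inlet_do_diurnal_mgL: float = 0.3
    flow_Lh: float = 1.5e6
    noise_sd_temperature_C: float = 0.15
    noise_sd_do_mgL: float = 0.1
    seasonal_peak_doy: int = 196  # mid-July thermal peak

    @model_validator(mode="after")
    def _check(self) -> "SyntheticForcingConfig":
        for name in ("seasonal_amplitude_C", "diurnal_amplitude_C",
                     "inlet_do_diurnal_mgL", "noise_sd_temperature_C",
                     "noise_sd_do_mgL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.flow_Lh <= 0:
            raise ValueError("flow_Lh must be strictly positive")
        return self


class ForcingConfig(_StrictModel):
    source: Literal["file", "synthetic"] = "synthetic"
    path: Optional[str] = None
    cadence: Literal["hourly", "daily"] = "hourly"
    synthetic: SyntheticForcingConfig = Field(default_factory=SyntheticForcingConfig)


class FishConfig(_StrictModel):
    initial_count: float = 100000.0
    initial_mean_weight_g: float = 100.0
    initial_sd_weight_g: float = 15.0
    params: BioenergeticParams = Field(default_factory=BioenergeticParams)


class FeedConfig(_StrictModel):
    spec: FeedSpec = Field(default_factory=FeedSpec)
    ration_mode: Literal["fraction_bw", "fixed", "table"] = "fraction_bw"
    ration_frac_bw: float = 0.015
    ration_g_per_fish: float = 2.0


class ScenarioConfig(_StrictModel):
    name: str = "A"
    variant: Literal["A", "B", "B1", "B2", "green", "welfare", "none"] = "A"
    horizon_d: float = 60.0
    supply_cutoff_h: Optional[float] = None  # open-loop cutoff, hours from start
    constant_supply_m3h: float = 2.4


class SimulationConfig(_StrictModel):
    """Top-level simulation document; see docs/methods.md for the defaults table."""

    geometry: RacewayGeometry
    start_date: _dt.date = _dt.date(2019, 10, 1)
    seed: int = 0
    time_step_growth_d: float = 1.0
    time_step_do_h: float = 1.0
    n_cells: int = 100
    forcing: ForcingConfig = Field(default_factory=ForcingConfig)
    fish: FishConfig = Field(default_factory=FishConfig)
    feed: FeedConfig = Field(default_factory=FeedConfig)
    do_model: DOModelConfig = Field(default_factory=DOModelConfig)
    control: ControlConfig = Field(default_factory=ControlConfig)
    management: ManagementConfig = Field(default_factory=ManagementConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.time_step_do_h > self.time_step_growth_d * 24.0:
            raise ValueError("DO time step must not exceed the growth time step")
        if self.n_cells < 2:
            raise ValueError("need at least 2 spatial cells")
        if self.time_step_growth_d <= 0 or self.time_step_do_h <= 0:
            raise ValueError("time steps must be positive")
        return self


def load_config(path) -> SimulationConfig:
    """Load a YAML or JSON simulation config, filling documented defaults.

    Unknown keys anywhere in the document are rejected with an error that
    names them; so are invariant violations (negative dimensions etc.).
    """
    from .errors import FormatError

    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise FormatError(f"could not parse config document: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError("config document must be a mapping")
    return build_config(data)


def build_config(data: dict) -> SimulationConfig:
    """Validate a config mapping into a :class:`SimulationConfig`."""
    try:
        return SimulationConfig(**data)
    except _PydanticValidationError as exc:
        keys = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            keys.append(f"{loc}: {err['msg']}")
        raise ConfigurationError(
            "invalid configuration — " + "; ".join(keys)
        ) from exc


def dump_config(config: SimulationConfig, path) -> None:
    """Write a config back to YAML; loading the dump yields an equal config."""
    data = config.model_dump(mode="json", exclude_none=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
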