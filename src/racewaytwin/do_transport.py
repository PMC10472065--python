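"""1-D dissolved-oxygen transport along the raceway.

The streamwise DO balance is an advection equation with two reaction terms —
atmospheric reaeration toward the saturation concentration and a distributed
respiration sink proportional to the local biomass density — plus a point
oxygen source at the inlet:

    ∂C/∂t = −(Q/A) ∂C/∂x + k_rear (Csat − C) − (R/A) ∂M/∂x

C in mg/L, Q in L/h, A in m², k_rear in 1/h, x in m, t in h. R is the
specific respiration rate in mg O2 per kg biomass per hour and ∂M/∂x the
biomass density in kg/m, so the sink closes to mg L⁻¹ h⁻¹ after the m³→L
conversion. The solver is an explicit first-order upwind scheme on a
node-centred grid over [0, length]; there is no diffusion term, so upwind
needs no outflow boundary condition and the inlet node is a Dirichlet
boundary carrying the river DO plus the point-source increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .config import DOModelConfig, ForcingSeries, RacewayGeometry
from .errors import CFLError, DomainError

__all__ = [
    "DOField",
    "BiomassProfile",
    "OxygenSource",
    "ReaerationParams",
    "csat",
    "source_increment",
    "distribute_biomass",
    "residence_time_h",
    "steady_state_profile",
    "simulate_do",
    "advance_interval",
]

# Benson–Krause freshwater equilibrium DO at 1 atm moist air (mg/L), the
# standard-table formulation in T_kelvin.
_BK = (-139.34411, 1.575701e5, -6.642308e7, 1.243800e10, -8.621949e11)


@dataclass
class ReaerationParams:
    k_rear_per_h: float = 0.1
    csat_formula: str = "benson-krause"
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.k_rear_per_h < 0:
            raise DomainError("k_rear must be non-negative")
        if self.csat_formula != "benson-krause":
            raise DomainError(f"unknown csat formula {self.csat_formula!r}")

    @classmethod
    def from_config(cls, cfg: DOModelConfig) -> "ReaerationParams":
        return cls(cfg.k_rear_per_h, cfg.csat_formula, cfg.pressure_atm)


@dataclass
class OxygenSource:
    """Point oxygen source at the raceway inlet.

    ``supply_m3_per_h`` is gasified-oxygen volume; delivered mass is
    supply × gas density × transfer efficiency.
    """

    supply_m3_per_h: float
    gas_density_kg_m3: float = 1.429
    efficiency: float = 0.9

    def __post_init__(self) -> None:
        if self.supply_m3_per_h < 0:
            raise DomainError("supply must be non-negative")
        if not (0 <= self.efficiency <= 1):
            raise DomainError("efficiency must lie in [0, 1]")

    @property
    def delivered_kg_per_h(self) -> float:
        return self.supply_m3_per_h * self.gas_density_kg_m3 * self.efficiency


@dataclass
class BiomassProfile:
    """Biomass density along the raceway plus its specific respiration rate."""

    x_m: np.ndarray
    density_kg_per_m: np.ndarray
    total_kg: float
    specific_respiration_mgO2_per_kg_h: float = 0.0

    def __post_init__(self) -> None:
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.density_kg_per_m = np.asarray(self.density_kg_per_m, dtype=float)
        if np.any(self.density_kg_per_m < 0):
            raise DomainError("biomass density must be non-negative")
        if self.specific_respiration_mgO2_per_kg_h < 0:
            raise DomainError("specific respiration must be non-negative")
        if self.total_kg > 0:
            integral = np.trapezoid(self.density_kg_per_m, self.x_m)
            if abs(integral - self.total_kg) > 1e-6 * self.total_kg:
                raise DomainError(
                    "biomass density does not integrate to the stated total"
                )


@dataclass
class DOField:
    """Solution C(x, t) on the space–time grid, plus any anoxia events."""

    x_m: np.ndarray
    time_h: np.ndarray
    C: np.ndarray  # shape (n_nodes, n_times)
    anoxia_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.x_m), len(self.time_h)):
            raise DomainError("DO field shape inconsistent with its grid")

    @property
    def outlet_mgL(self) -> np.ndarray:
        return self.C[-1, :]

    @property
    def inlet_mgL(self) -> np.ndarray:
        return self.C[0, :]


def csat(T: float, params: Optional[ReaerationParams] = None):
    """Freshwater DO saturation concentration (mg/L), Benson–Krause form.

    Valid for T in [0, 40] °C; scaled linearly by pressure in atmospheres.
    Strictly decreasing in temperature.
    """
    p = params or ReaerationParams()
    T_arr = np.asarray(T, dtype=float)
    if np.any((T_arr < 0.0) | (T_arr > 40.0)):
        raise DomainError(f"temperature {T!r} outside csat validity range [0, 40] °C")
    tk = T_arr + 273.15
    a0, a1, a2, a3, a4 = _BK
    ln_c = a0 + a1 / tk + a2 / tk**2 + a3 / tk**3 + a4 / tk**4
    out = np.exp(ln_c) * p.pressure_atm
    return float(out) if np.ndim(T) == 0 else out


def source_increment(source: OxygenSource, Q_Lh: float) -> float:
    """Concentration increment (mg/L) of the inlet point source at flow Q."""
    if Q_Lh <= 0:
        raise DomainError("flow must be strictly positive")
    return source.delivered_kg_per_h * 1e6 / Q_Lh  # kg/h → mg/h, over L/h


def distribute_biomass(
    M_total: float,
    geometry: RacewayGeometry,
    mode: str = "uniform",
    n_nodes: int = 101,
    specific_respiration: float = 0.0,
) -> BiomassProfile:
    """Spread total biomass along the raceway (uniform density only)."""
    if M_total < 0:
        raise DomainError("biomass must be non-negative")
    if mode != "uniform":
        raise DomainError(f"unknown biomass distribution mode {mode!r}")
    x = np.linspace(0.0, geometry.length_m, n_nodes)
    dens = np.full(n_nodes, M_total / geometry.length_m)
    return BiomassProfile(x, dens, M_total, specific_respiration)


def residence_time_h(geometry: RacewayGeometry, Q_Lh: float) -> float:
    """Hydraulic residence time volume/Q in hours."""
    if Q_Lh <= 0:
        raise DomainError("flow must be strictly positive")
    return geometry.volume_m3 / (Q_Lh / 1000.0)


def steady_state_profile(
    C0: float,
    Q_Lh: float,
    geometry: RacewayGeometry,
    biomass: BiomassProfile,
    params: ReaerationParams,
    T_C: float = 15.0,
    x_m: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Analytic steady profile for constant inputs and uniform biomass.

    With s the volumetric sink (mg L⁻¹ h⁻¹) and u = Q/A the velocity:
    k_rear = 0 gives the linear profile C0 − s·x/u; k_rear > 0 gives
    relaxation toward C* = Csat − s/k_rear at rate k_rear/u per metre.
    Serves as the independent oracle for the upwind solver.
    """
    x = np.asarray(biomass.x_m if x_m is None else x_m, dtype=float)
    u = (Q_Lh / 1000.0) / geometry.cross_section_m2  # m/h
    dens = biomass.density_kg_per_m
    if biomass.total_kg > 0 and np.ptp(dens) > 1e-9 * max(np.max(dens), 1e-30):
        raise DomainError("analytic profile requires uniform biomass density")
    dens0 = float(dens[0]) if len(dens) else 0.0
    s = (
        biomass.specific_respiration_mgO2_per_kg_h
        * dens0
        / (geometry.cross_section_m2 * 1000.0)
    )  # mg L^-1 h^-1
    k = params.k_rear_per_h
    if k == 0:
        return C0 - s * x / u
    c_star = csat(T_C, params) - s / k
    return c_star + (C0 - c_star) * np.exp(-k * x / u)


def max_stable_dt_h(geometry: RacewayGeometry, Q_Lh: float, dx_m: float) -> float:
    u = (Q_Lh / 1000.0) / geometry.cross_section_m2
    return dx_m / u


def advance_interval(
    C: np.ndarray,
    c_in: float,
    duration_h: float,
    dt_h: float,
    u_m_per_h: float,
    dx_m: float,
    k_rear: float,
    csat_mgL: float,
    sink_mgL_per_h: np.ndarray,
    record_all: bool = False,
    track_budget: bool = True,
):
    """Advance the upwind scheme over one constant-forcing interval.

    Returns ``(C_end, min_C, snapshots, budget)`` where ``min_C`` is the
    minimum concentration over all nodes and sub-steps, ``snapshots`` the
    per-sub-step states when ``record_all``, and ``budget`` the exact
    discrete mass-accounting terms of the interval (per unit cross-section
    volume; multiply by A·dx·1000 for mass): inflow/outflow advective terms,
    reaeration, respiration sink, clipped (anoxia) correction. Budget
    tracking can be switched off for controller predictions.
    """
    n_sub = max(1, int(math.ceil(duration_h / dt_h - 1e-12)))
    dt = duration_h / n_sub
    lam = u_m_per_h * dt / dx_m
    if lam > 1.0 + 1e-12:
        raise CFLError(
            f"CFL violation: u·dt/dx = {lam:.3f} > 1; "
            f"largest admissible dt is {dx_m / u_m_per_h:.6g} h",
            dt_max_h=dx_m / u_m_per_h,
        )
    C = C.copy()
    C[0] = c_in
    min_c = float(C.min())
    snaps = []
    adv_out = rear = clipped = 0.0
    # the update is affine in the state: new = a·C_i + lam·C_{i-1} + const
    a = 1.0 - lam - dt * k_rear
    const = dt * (k_rear * csat_mgL - sink_mgL_per_h[1:])
    n_int = len(C) - 1
    for _ in range(n_sub):
        if track_budget:
            adv_out += lam * C[-1]
            rear += dt * k_rear * (csat_mgL * n_int - float(C[1:].sum()))
        new = a * C[1:] + lam * C[:-1] + const
        m = float(new.min())
        if m < 0.0:
            neg = new < 0.0
            clipped += float(-new[neg].sum())
            new[neg] = 0.0
            m = 0.0
        C[1:] = new
        if m < min_c:
            min_c = m
        if record_all:
            snaps.append(C.copy())
    budget = {
        "advection_in": n_sub * lam * c_in,
        "advection_out": adv_out,
        "reaeration": rear,
        "respiration": n_sub * dt * float(sink_mgL_per_h[1:].sum()),
        "clipped": clipped,
        "n_sub": n_sub,
        "dt_h": dt,
    }
    return C, min_c, snaps, budget


def simulate_do(
    forcing: ForcingSeries,
    biomass: Union[BiomassProfile, Sequence[BiomassProfile], Callable[[int], BiomassProfile]],
    source_schedule: Union[OxygenSource, Callable[[float], OxygenSource], None],
    params: ReaerationParams,
    geometry: RacewayGeometry,
    dx_m: float = 2.0,
    dt_h: Optional[float] = None,
    C0: Optional[np.ndarray] = None,
    cfl_safety: float = 0.9,
    record_substeps: bool = False,
) -> DOField:
    """Solve the DO transport equation over the forcing horizon.

    Forcing, biomass and source are held piecewise-constant over each forcing
    interval. The inlet boundary is river DO plus the point-source increment.
    Negative concentrations are clipped to zero and logged as anoxia events
    on the returned field rather than raised. If ``dt_h`` is omitted it is
    chosen from the CFL bound with the given safety factor; an explicit
    ``dt_h`` that violates CFL raises :class:`CFLError` stating the largest
    admissible step.
    """
    n_nodes = int(round(geometry.length_m / dx_m)) + 1
    x = np.linspace(0.0, geometry.length_m, n_nodes)
    dx_m = float(x[1] - x[0])  # effective spacing when length is not a multiple
    u_max = (float(np.max(forcing.flow_Lh)) / 1000.0) / geometry.cross_section_m2
    dt_admissible = dx_m / u_max
    if dt_h is None:
        dt_h = cfl_safety * dt_admissible
    elif dt_h > dt_admissible + 1e-12:
        raise CFLError(
            f"dt = {dt_h:g} h violates the CFL bound; largest admissible dt "
            f"is {dt_admissible:.6g} h for dx = {dx_m:g} m",
            dt_max_h=dt_admissible,
        )

    def biomass_at(i: int) -> BiomassProfile:
        if isinstance(biomass, BiomassProfile):
            return biomass
        if callable(biomass):
            return biomass(i)
        return biomass[min(i, len(biomass) - 1)]

    def source_at(t_h: float) -> OxygenSource:
        if source_schedule is None:
            return OxygenSource(0.0)
        if isinstance(source_schedule, OxygenSource):
            return source_schedule
        return source_schedule(t_h)

    b0 = biomass_at(0)
    q0 = forcing.flow_Lh[0]
    c_in0 = forcing.inlet_DO_mgL[0] + source_increment(source_at(forcing.time_h[0]), q0)
    C = np.full(n_nodes, c_in0) if C0 is None else np.asarray(C0, dtype=float).copy()
    C[0] = c_in0

    times = [float(forcing.time_h[0])]
    states = [C.copy()]
    events: list = []

    for i in range(len(forcing) - 1):
        t0, t1 = forcing.time_h[i], forcing.time_h[i + 1]
        T = forcing.temperature_C[i]
        Q = forcing.flow_Lh[i]
        u = (Q / 1000.0) / geometry.cross_section_m2
        prof = biomass_at(i)
        sink = _sink_profile(prof, x, geometry)
        c_in = forcing.inlet_DO_mgL[i] + source_increment(source_at(t0), Q)
        C, _, snaps, budget = advance_interval(
            C, c_in, t1 - t0, dt_h, u, dx_m, params.k_rear_per_h,
            csat(T, params), sink, record_all=record_substeps,
        )
        if budget["clipped"] > 0:
            events.append({"kind": "anoxia", "time_h": float(t1),
                           "clipped_mgL": budget["clipped"]})
        if record_substeps:
            sub_dt = budget["dt_h"]
            for j, s in enumerate(snaps):
                times.append(float(t0 + (j + 1) * sub_dt))
                states.append(s)
        else:
            times.append(float(t1))
            states.append(C.copy())

    return DOField(x_m=x, time_h=np.asarray(times), C=np.column_stack(states),
                   anoxia_events=events)


def _sink_profile(prof: BiomassProfile, x: np.ndarray, geometry: RacewayGeometry) -> np.ndarray:
    """Volumetric respiration sink (mg L⁻¹ h⁻¹) on the solver grid."""
    if len(prof.x_m) == len(x) and np.allclose(prof.x_m, x):
        dens = prof.density_kg_per_m
    else:
        dens = np.interp(x, prof.x_m, prof.density_kg_per_m)
    return (
        prof.specific_respiration_mgO2_per_kg_h
        * dens
        / (geometry.cross_section_m2 * 1000.0)
    )
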