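"""Synthetic forcing generator.

Emulates the boundary conditions of an Alpine river-fed raceway: water
temperature with a seasonal cosine (mid-July peak, declining toward winter)
plus a diurnal sine and Gaussian noise; inlet DO tracking the temperature-
dependent saturation concentration (river water near equilibrium with the
atmosphere) with its own diurnal oscillation and noise; constant flow.

The generator is seeded and fully reproducible; it makes no attempt to
emulate flood events, turbidity or upstream biological oxygen demand.
"""

from __future__ import annotations

import datetime as _dt
from typing import Optional

import numpy as np

from .config import ForcingSeries, SyntheticForcingConfig
from .do_transport import ReaerationParams, csat
from .errors import DomainError

__all__ = ["synthetic_forcing"]


def synthetic_forcing(
    spec: SyntheticForcingConfig,
    days: float,
    seed: int = 0,
    start_date: Optional[_dt.date] = None,
    pressure_atm: float = 1.0,
) -> ForcingSeries:
    """Generate an hourly :class:`ForcingSeries` for ``days`` days.

    Temperature: mean + seasonal·cos(2π(doy − peak)/365) + diurnal·sin(2π t/24)
    + noise, clipped to the physical range. Inlet DO: saturation at the
    generated temperature times ``inlet_do_saturation`` (or a fixed mean if
    ``inlet_do_mean_mgL`` is set) plus a diurnal sine and noise. Raises a
    validation error if the parameters would produce negative DO.
    """
    if days <= 0:
        raise DomainError("days must be strictly positive")
    rng = np.random.default_rng(seed)
    n = int(round(days * 24)) + 1
    t_h = np.arange(n, dtype=float)

    start = start_date or _dt.date(2019, 10, 1)
    doy = start.timetuple().tm_yday + t_h / 24.0
    seasonal = spec.seasonal_amplitude_C * np.cos(
        2.0 * np.pi * (doy - spec.seasonal_peak_doy) / 365.0
    )
    diurnal = spec.diurnal_amplitude_C * np.sin(2.0 * np.pi * t_h / 24.0)
    T = (
        spec.mean_temperature_C
        + seasonal
        + diurnal
        + rng.normal(0.0, spec.noise_sd_temperature_C, n)
    )
    T = np.clip(T, -0.5, 39.5)

    params = ReaerationParams(pressure_atm=pressure_atm)
    if spec.inlet_do_mean_mgL is not None:
        do_base = np.full(n, spec.inlet_do_mean_mgL)
    else:
        do_base = spec.inlet_do_saturation * csat(np.clip(T, 0.0, 40.0), params)
    do = (
        do_base
        + spec.inlet_do_diurnal_mgL * np.sin(2.0 * np.pi * t_h / 24.0)
        + rng.normal(0.0, spec.noise_sd_do_mgL, n)
    )
    if np.any(do < 0):
        raise DomainError(
            "synthetic forcing parameters produce negative inlet DO; "
            "reduce amplitudes or noise"
        )

    return ForcingSeries(
        time_h=t_h,
        temperature_C=T,
        inlet_DO_mgL=do,
        flow_Lh=np.full(n, spec.flow_Lh),
        start=_dt.datetime.combine(start, _dt.time()),
    )
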