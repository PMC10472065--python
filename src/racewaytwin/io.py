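"""CSV readers and writers for forcing series and simulation outputs.

Dialect: comma-separated, dot decimal, UTF-8, one header row — matching the
style of typical farm sensor exports. Floats are written with 12 significant
digits so a round trip reproduces values to better than 1e-9 relative.
"""

from __future__ import annotations

import os
import numpy as np
import pandas as pd

from .config import FeedSpec, ForcingSeries
from .errors import DataGapError, DomainError, FormatError, RacewayError

_FORCING_COLUMNS = ("timestamp", "temperature", "inlet_DO", "flow")
_FLOAT_FMT = "%.12g"
_MAX_GAP_STEPS = 3


def read_forcing_csv(path, cadence: str = "hourly") -> ForcingSeries:
    """Read a forcing CSV into a validated :class:`ForcingSeries`.

    The file must carry columns ``timestamp,temperature,inlet_DO,flow``.
    Timestamps may be ISO datetimes or plain numbers (hours for hourly
    cadence, days for daily). Rows finer than the cadence are aggregated by
    mean onto the cadence grid; gaps of up to three grid steps are linearly
    interpolated, longer gaps raise :class:`DataGapError` naming the
    interval.
    """
    if cadence not in ("hourly", "daily"):
        raise ValueError("cadence must be 'hourly' or 'daily'")
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"could not parse forcing CSV {path}: {exc}") from exc
    missing = [c for c in _FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"forcing CSV {path} is missing column(s): {', '.join(missing)}"
        )
    if len(df) == 0:
        raise FormatError(f"forcing CSV {path} has no data rows")

    step_h = 1.0 if cadence == "hourly" else 24.0
    ts_raw = df["timestamp"]
    start = None
    if pd.api.types.is_numeric_dtype(ts_raw):
        t_h = ts_raw.to_numpy(dtype=float) * (1.0 if cadence == "hourly" else 24.0)
    else:
        try:
            ts = pd.to_datetime(ts_raw, format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"unparseable timestamps in {path}: {exc}") from exc
        start = ts.iloc[0].to_pydatetime()
        t_h = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    if np.any(np.diff(t_h) <= 0):
        raise DomainError(f"timestamps in {path} are not strictly increasing")

    # Snap to the cadence grid; average any sub-cadence rows in each slot.
    slot = np.round(t_h / step_h).astype(int) if _is_regular(t_h, step_h) else (
        np.floor(t_h / step_h).astype(int)
    )
    work = pd.DataFrame(
        {
            "slot": slot,
            "temperature": df["temperature"].to_numpy(dtype=float),
            "inlet_DO": df["inlet_DO"].to_numpy(dtype=float),
            "flow": df["flow"].to_numpy(dtype=float),
        }
    )
    agg = work.groupby("slot", sort=True).mean()
    full = np.arange(agg.index[0], agg.index[-1] + 1)
    agg = agg.reindex(full)

    isna = agg["temperature"].isna().to_numpy()
    if isna.any():
        _check_gaps(isna, full, step_h, path)
        agg = agg.interpolate(method="linear", limit_area="inside")

    return ForcingSeries(
        time_h=full * step_h,
        temperature_C=agg["temperature"].to_numpy(),
        inlet_DO_mgL=agg["inlet_DO"].to_numpy(),
        flow_Lh=agg["flow"].to_numpy(),
        start=start,
    )


def _is_regular(t_h: np.ndarray, step_h: float) -> bool:
    return bool(np.all(np.abs(t_h / step_h - np.round(t_h / step_h)) < 1e-6))


def _check_gaps(isna: np.ndarray, slots: np.ndarray, step_h: float, path) -> None:
    run = 0
    run_start = None
    for i, bad in enumerate(list(isna) + [False]):
        if bad:
            if run == 0:
                run_start = i
            run += 1
        else:
            if run > _MAX_GAP_STEPS:
                t0 = slots[run_start] * step_h
                t1 = slots[run_start + run - 1] * step_h
                raise DataGapError(
                    f"forcing CSV {path} has a {run}-step gap "
                    f"(t = {t0:g} h to {t1:g} h) exceeding the "
                    f"{_MAX_GAP_STEPS}-step interpolation limit",
                    gap_start=t0,
                    gap_end=t1,
                )
            run = 0


def write_forcing_csv(series: ForcingSeries, path, cadence: str = "hourly") -> None:
    """Inverse of :func:`read_forcing_csv` for numeric timestamps."""
    step = 1.0 if cadence == "hourly" else 24.0
    pd.DataFrame(
        {
            "timestamp": series.time_h / step,
            "temperature": series.temperature_C,
            "inlet_DO": series.inlet_DO_mgL,
            "flow": series.flow_Lh,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_field_csv(field, path) -> None:
    """Write a DO field in long format with columns ``x_m,time,DO_mgL``.

    One row per (node, time) pair; refuses an empty grid.
    """
    nx, nt = field.C.shape
    if nx == 0 or nt == 0:
        raise DomainError("cannot write an empty DO field")
    x = np.repeat(field.x_m, nt)
    t = np.tile(field.time_h, nx)
    c = field.C.reshape(-1)
    try:
        pd.DataFrame({"x_m": x, "time": t, "DO_mgL": c}).to_csv(
            path, index=False, float_format=_FLOAT_FMT
        )
    except OSError as exc:
        raise RacewayError(f"cannot write field CSV to {path}: {exc}") from exc


def read_field_csv(path):
    """Read a long-format field CSV back into a DOField (round-trip partner)."""
    from .do_transport import DOField

    df = pd.read_csv(path)
    missing = [c for c in ("x_m", "time", "DO_mgL") if c not in df.columns]
    if missing:
        raise FormatError(f"field CSV {path} missing column(s): {', '.join(missing)}")
    x = np.unique(df["x_m"].to_numpy())
    t = np.unique(df["time"].to_numpy())
    if len(df) != len(x) * len(t):
        raise FormatError(f"field CSV {path} is not a complete (x, time) grid")
    piv = df.pivot(index="x_m", columns="time", values="DO_mgL")
    piv = piv.sort_index().sort_index(axis=1)
    return DOField(x_m=x, time_h=t, C=piv.to_numpy())


def read_feed_plan_csv(path) -> pd.DataFrame:
    """Read a feed plan CSV: ``date,ration_g_per_fish,protein_frac,lipid_frac,carb_frac``."""
    df = pd.read_csv(path)
    required = ("date", "ration_g_per_fish", "protein_frac", "lipid_frac", "carb_frac")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"feed plan CSV {path} missing column(s): {', '.join(missing)}")
    # validate each row's composition through FeedSpec
    for _, row in df.iterrows():
        FeedSpec(
            protein_frac=row["protein_frac"],
            lipid_frac=row["lipid_frac"],
            carb_frac=row["carb_frac"],
        )
    return df


def write_growth_csv(traj, path) -> None:
    """Growth trajectory CSV: time, weight band, biomass and metabolic loads."""
    pd.DataFrame(
        {
            "time": traj.time_d,
            "mean_weight_g": traj.mean_weight_g,
            "lo_weight_g": traj.lo_weight_g,
            "hi_weight_g": traj.hi_weight_g,
            "biomass_kg": traj.biomass_kg,
            "respiration_mgO2_h": traj.respiration_mgO2_h,
            "tan_g_d": traj.tan_g_d,
            "co2_g_d": traj.co2_g_d,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def ensure_writable_dir(directory) -> None:
    os.makedirs(directory, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise RacewayError(f"directory {directory} is not writable")
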