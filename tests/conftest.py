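"""Shared fixtures: a pilot-like raceway, default parameters, forcing builders."""

import numpy as np
import pytest

from racewaytwin import (
    BioenergeticParams,
    FeedPlan,
    FeedSpec,
    FishCohort,
    ForcingSeries,
    RacewayGeometry,
)
from racewaytwin.config import build_config


@pytest.fixture
def geometry() -> RacewayGeometry:
    # 200 m × 8 m flow-through raceway; 1 m depth gives a ~1 h residence
    # at the ~1.5e6 L/h flow used throughout the tests
    return RacewayGeometry(length_m=200.0, width_m=8.0, depth_m=1.0)


@pytest.fixture
def params() -> BioenergeticParams:
    return BioenergeticParams()


@pytest.fixture
def feed_plan() -> FeedPlan:
    return FeedPlan(feed=FeedSpec(), ration_frac_bw=0.015)


@pytest.fixture
def cohort() -> FishCohort:
    return FishCohort(count=50000, mean_weight_g=200.0, sd_weight_g=30.0)


def constant_forcing(hours: float, T: float = 12.0, do: float = 10.5,
                     Q: float = 1.5e6, step_h: float = 1.0) -> ForcingSeries:
    n = int(round(hours / step_h)) + 1
    t = np.arange(n) * step_h
    return ForcingSeries(t, np.full(n, T), np.full(n, do), np.full(n, Q))


@pytest.fixture
def make_forcing():
    return constant_forcing


def oxygen_accountant(field, geometry, Q, k_rear, cs, sink):
    """Independent oxygen budget from a recorded field, in mg.

    Sums fluxes over every recorded step using pre-step states: inflow and
    outflow by advection, reaeration and respiration volume terms, against
    the storage change of the interior cells. Returns (residual, scale).
    """
    dx = field.x_m[1] - field.x_m[0]
    cell_L = geometry.cross_section_m2 * dx * 1000.0
    dt = np.diff(field.time_h)
    C = field.C
    inflow = np.sum(Q * C[0, :-1] * dt)
    outflow = np.sum(Q * C[-1, :-1] * dt)
    rear = np.sum((k_rear * (cs - C[1:, :-1])).sum(axis=0) * dt) * cell_L
    resp = np.sum(sink[1:].sum() * dt) * cell_L
    storage = (C[1:, -1] - C[1:, 0]).sum() * cell_L
    residual = inflow - outflow + rear - resp - storage
    return residual, max(inflow, outflow)


def base_config(**overrides) -> dict:
    cfg = {"geometry": {"depth_m": 1.0}, "seed": 1}
    cfg.update(overrides)
    return cfg


@pytest.fixture
def make_config():
    def _make(**overrides):
        return build_config(base_config(**overrides))

    return _make
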