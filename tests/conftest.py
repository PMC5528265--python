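"""Shared fixtures: tiny hand-built forcings and one scaled-down cohort run."""

from __future__ import annotations

import numpy as np
import pytest

from turtledrift.grids import ForcingSeries, Grid
from turtledrift.params import SpeciesParams
from turtledrift.simulation import build_release_schedule, run_simulation
from turtledrift.synthetic import SyntheticForcingConfig, make_synthetic_forcing


@pytest.fixture(scope="session")
def species() -> SpeciesParams:
    return SpeciesParams()


def make_uniform_forcing(
    nlon: int = 8,
    nlat: int = 6,
    days: int = 30,
    lon0: float = 0.0,
    lat0: float = 0.0,
    step: float = 1.0,
    u: float = 0.0,
    v: float = 0.0,
    sst: float = 28.0,
    npp: float = 100.0,
    land: np.ndarray | None = None,
) -> ForcingSeries:
    """Spatially/temporally uniform forcing for unit tests."""
    grid = Grid(lon0 + np.arange(nlon) * step, lat0 + np.arange(nlat) * step, land)
    shape = (days, nlat, nlon)
    return ForcingSeries(
        grid=grid,
        times=np.datetime64("2000-01-01", "D") + np.arange(days),
        u=np.full(shape, float(u)),
        v=np.full(shape, float(v)),
        sst=np.full(shape, float(sst)),
        npp=np.full(shape, float(npp)),
    )


@pytest.fixture()
def uniform_forcing() -> ForcingSeries:
    return make_uniform_forcing()


@pytest.fixture(scope="session")
def small_synth_config() -> SyntheticForcingConfig:
    """Reduced basin for fast simulation tests."""
    return SyntheticForcingConfig(lon_max=200.0, step=2.0, period_days=120)


@pytest.fixture(scope="session")
def small_synth_forcing(small_synth_config) -> ForcingSeries:
    return make_synthetic_forcing(small_synth_config)


@pytest.fixture(scope="session")
def cohort_runs():
    """Scaled-down study runs: 500 agents, 6 years, passive and active.

    Session-scoped because the active run takes a noticeable fraction of a
    minute; every emergent-behavior check shares these two runs.
    """
    forcing = make_synthetic_forcing()
    schedule = build_release_schedule(
        500, ("2000-06-01", "2000-11-30"), "2000-09-15", 30.0,
        (137.0, 13.5), 0.25, seed=1,
    )
    runs = {
        mode: run_simulation(forcing, schedule, mode=mode, years=6, seed=2)
        for mode in ("passive", "active")
    }
    return {"forcing": forcing, "schedule": schedule, **runs}
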