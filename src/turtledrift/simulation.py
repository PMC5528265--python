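"""Agent life cycle: release, daily advection, cold mortality, recording.

Agents are released from a small offshore box on dates drawn from a
truncated normal distribution, then stepped daily under the velocity over
ground Vg = Vc + Vs (surface current plus habitat-driven swimming; Vs = 0
in passive mode).  A turtle dies when it experiences water colder than its
age-dependent critical temperature T1 for ``cold_threshold_days``
consecutive days; an agent crossing the domain boundary is frozen and
flagged as exited.  All randomness flows through per-purpose streams
spawned from a single run seed, so runs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import allometry
from .grids import EARTH_RADIUS, DomainError, ForcingSeries, Grid, bilinear
from .habitat import habitat_field
from .movement import KAPPA_MAX, sample_headings, swimming_velocity
from .params import ConfigError, SpeciesParams

__all__ = [
    "ALIVE",
    "DEAD",
    "EXITED",
    "ReleaseSchedule",
    "TurtleState",
    "TrajectorySet",
    "build_release_schedule",
    "step_position",
    "update_cold_mortality",
    "run_simulation",
]

DEG = np.pi / 180.0
M_PER_DEG = EARTH_RADIUS * DEG  # meters per degree of latitude
SECONDS_PER_DAY = 86_400.0

ALIVE, DEAD, EXITED = 0, 1, 2


@dataclass
class ReleaseSchedule:
    """Release dates and positions for a cohort of ``n`` agents."""

    dates: np.ndarray  # datetime64[D], shape (n,)
    lons: np.ndarray
    lats: np.ndarray
    box_center: tuple[float, float]
    box_width: float

    @property
    def n(self) -> int:
        return self.dates.size


def build_release_schedule(
    n: int,
    window: tuple,
    peak,
    sigma_days: float,
    box_center: tuple[float, float],
    box_width: float = 0.25,
    seed: int | np.random.SeedSequence | None = 0,
) -> ReleaseSchedule:
    """Draw ``n`` release dates and positions.

    Dates follow a normal distribution centered on ``peak`` with standard
    deviation ``sigma_days``, truncated to ``window`` and rounded to whole
    days; positions are uniform in the ``box_width``-degree square around
    ``box_center`` (lon, lat).  Deterministic for a given seed.
    """
    if n < 1:
        raise ConfigError("n must be at least 1")
    if sigma_days <= 0:
        raise ConfigError("sigma_days must be positive")
    start = np.datetime64(window[0], "D")
    end = np.datetime64(window[1], "D")
    if end < start:
        raise ConfigError("empty release window")
    peak = np.datetime64(peak, "D")
    rng = np.random.default_rng(seed)
    lo = (start - peak) / np.timedelta64(1, "D")
    hi = (end - peak) / np.timedelta64(1, "D") + 1.0  # days are rounded down
    offsets = stats.truncnorm.rvs(
        lo / sigma_days, hi / sigma_days, loc=0.0, scale=sigma_days,
        size=n, random_state=rng,
    )
    dates = peak + np.floor(offsets).astype("timedelta64[D]")
    dates = np.minimum(np.maximum(dates, start), end)
    half = box_width / 2.0
    lons = box_center[0] + rng.uniform(-half, half, size=n)
    lats = box_center[1] + rng.uniform(-half, half, size=n)
    return ReleaseSchedule(dates=dates, lons=lons, lats=lats,
                           box_center=tuple(box_center), box_width=box_width)


@dataclass
class TurtleState:
    """State of one agent (scalar API used by the per-step operations)."""

    id: int
    lon: float
    lat: float
    birth_date: np.datetime64
    age_days: int = 0
    alive: bool = True
    cold_days: int = 0
    death_date: np.datetime64 | None = None


def step_position(state: TurtleState, vg, dt: float = SECONDS_PER_DAY):
    """New (lon, lat) after one step at velocity-over-ground ``vg``.

    Latitude advances by vg_north*dt metrically; the longitude conversion
    uses the midpoint latitude of the step (one Heun pass), so a purely
    meridional displacement is latitude-independent.
    """
    if not state.alive:
        raise ValueError("dead agents are never stepped")
    dlat = vg[1] * dt / M_PER_DEG
    lat_mid = state.lat + dlat / 2.0
    dlon = vg[0] * dt / (M_PER_DEG * np.cos(lat_mid * DEG))
    return state.lon + dlon, state.lat + dlat


def update_cold_mortality(
    state: TurtleState,
    tw: float,
    t1: float,
    threshold: int = 10,
    mode: str = "consecutive",
) -> TurtleState:
    """Update the cold-exposure counter and the alive flag of one agent.

    In the default consecutive mode the counter resets on any day with
    tw >= t1; in cumulative mode it only ever grows.  The agent dies the
    day the counter reaches ``threshold``.
    """
    if not state.alive:
        raise ValueError("dead agents are not updated")
    if tw < t1:
        state.cold_days += 1
    elif mode == "consecutive":
        state.cold_days = 0
    if state.cold_days >= threshold:
        state.alive = False
        state.death_date = state.birth_date + np.timedelta64(state.age_days, "D")
    return state


@dataclass
class TrajectorySet:
    """Per-agent, per-day records of a simulation.

    Record arrays have shape (n_agents, n_days); ``recorded`` marks the
    days between an agent's release and its death, exit or the end of the
    simulation.  Swimming and current components satisfy
    u_ground = u_current + u_swim for every record by construction.
    """

    dates: np.ndarray
    birth_dates: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    tw: np.ndarray
    h: np.ndarray
    ht: np.ndarray
    hf: np.ndarray
    us_east: np.ndarray
    us_north: np.ndarray
    uc_east: np.ndarray
    uc_north: np.ndarray
    alive: np.ndarray
    recorded: np.ndarray
    status: np.ndarray
    death_dates: np.ndarray
    mode: str = "active"
    meta: dict = field(default_factory=dict)

    FIELDS = ("lon", "lat", "tw", "h", "ht", "hf",
              "us_east", "us_north", "uc_east", "uc_north")

    @property
    def n_agents(self) -> int:
        return self.birth_dates.size

    def ages_years(self) -> np.ndarray:
        """Age (years) of every agent on every simulated day."""
        d = (self.dates[None, :] - self.birth_dates[:, None]) / np.timedelta64(1, "D")
        return d / allometry.DAYS_PER_YEAR

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per recorded agent-day."""
        idx_agent, idx_day = np.nonzero(self.recorded)
        df = pd.DataFrame({"agent": idx_agent, "date": self.dates[idx_day]})
        for name in self.FIELDS:
            df[name] = getattr(self, name)[idx_agent, idx_day]
        df["alive"] = self.alive[idx_agent, idx_day]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mode: str = "active") -> "TrajectorySet":
        """Rebuild a TrajectorySet from a saved long-format table."""
        if df.empty:
            raise ValueError("empty trajectory table")
        df = df.sort_values(["agent", "date"])
        agents = np.unique(df["agent"].to_numpy())
        dates = np.sort(np.unique(df["date"].to_numpy().astype("datetime64[D]")))
        n, nd = agents.size, dates.size
        amap = {a: k for k, a in enumerate(agents)}
        ia = df["agent"].map(amap).to_numpy()
        iday = ((df["date"].to_numpy().astype("datetime64[D]") - dates[0])
                / np.timedelta64(1, "D")).astype(int)
        arrays = {name: np.full((n, nd), np.nan) for name in cls.FIELDS}
        for name in cls.FIELDS:
            arrays[name][ia, iday] = df[name].to_numpy(dtype=float)
        alive = np.zeros((n, nd), dtype=bool)
        alive[ia, iday] = df["alive"].to_numpy(dtype=bool)
        recorded = np.zeros((n, nd), dtype=bool)
        recorded[ia, iday] = True
        birth = np.array([dates[recorded[k]].min() for k in range(n)],
                         dtype="datetime64[D]")
        status = np.zeros(n, dtype=np.int8)
        death_dates = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
        for k in range(n):
            days = np.nonzero(recorded[k])[0]
            if days.size and not alive[k, days[-1]]:
                status[k] = DEAD
                death_dates[k] = dates[days[-1]]
        return cls(dates=dates, birth_dates=birth, alive=alive, recorded=recorded,
                   status=status, death_dates=death_dates, mode=mode, **arrays)

    @classmethod
    def from_csv(cls, path, mode: str = "active") -> "TrajectorySet":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls.from_dataframe(df, mode=mode)

    def to_netcdf(self, path) -> None:
        import xarray as xr

        data = {name: (("agent", "time"), getattr(self, name)) for name in self.FIELDS}
        data["alive"] = (("agent", "time"), self.alive.astype("i1"))
        data["recorded"] = (("agent", "time"), self.recorded.astype("i1"))
        data["status"] = (("agent",), self.status)
        ds = xr.Dataset(
            data,
            coords={"time": self.dates.astype("datetime64[ns]"),
                    "agent": np.arange(self.n_agents)},
            # "mode" would shadow the scipy netCDF file-mode attribute
            attrs={"run_mode": self.mode,
                   **{k: v for k, v in self.meta.items() if np.isscalar(v)}},
        )
        ds.to_netcdf(path, engine="scipy")


def _candidate_step(grid: Grid, lon0, lat0, lon1, lat1, coast_mode: str):
    """Resolve tentative positions against coast and domain boundary.

    Returns (lon, lat, exited).  Free-slip drops the cross-shore component
    of a move that would beach; "reflect" mirrors it about the pre-step
    position; both fall back to staying put.
    """
    inside = grid.contains(lon1, lat1)
    exited = ~inside
    lon1 = np.where(inside, lon1, lon0)
    lat1 = np.where(inside, lat1, lat0)
    beached = inside & grid.is_land(lon1, lat1)
    if np.any(beached):
        if coast_mode == "reflect":
            alt_lon, alt_lat = 2 * lon0 - lon1, 2 * lat0 - lat1
        else:  # free slip: cancel the offending component
            alt_lon, alt_lat = lon0, lat0
        for cand_lon, cand_lat in ((lon1, alt_lat), (alt_lon, lat1)):
            ok = (beached & grid.contains(cand_lon, cand_lat)
                  & ~grid.is_land(np.where(beached, cand_lon, lon0),
                                  np.where(beached, cand_lat, lat0)))
            lon1 = np.where(ok, cand_lon, lon1)
            lat1 = np.where(ok, cand_lat, lat1)
            beached = beached & ~ok
        lon1 = np.where(beached, lon0, lon1)
        lat1 = np.where(beached, lat0, lat1)
    return lon1, lat1, exited


def run_simulation(
    forcing: ForcingSeries,
    schedule: ReleaseSchedule,
    params: SpeciesParams = SpeciesParams(),
    mode: str = "active",
    years: float = 18.0,
    seed: int | np.random.SeedSequence = 0,
    cold_threshold_days: int = 10,
    cold_mode: str = "consecutive",
    coast_mode: str = "slip",
    age_bin_years: float = 0.1,
    kappa_max: float = KAPPA_MAX,
) -> TrajectorySet:
    """Run the daily dispersal simulation and return the trajectory records.

    In active mode each living agent, every day, senses the habitat index
    and its gradient at its position (age-specific fields, bilinearly
    interpolated from cell centers), draws a von Mises heading, swims at
    Vm(age)*(1-h) and drifts with the current; in passive mode the
    swimming velocity is identically zero and no habitat is evaluated.
    Bitwise reproducible for a fixed seed.
    """
    if mode not in ("active", "passive"):
        raise ConfigError(f"unknown mode {mode!r}")
    if years < 1:
        raise ConfigError("simulation must span at least one year")
    grid = forcing.grid
    if not np.all(grid.contains(schedule.lons, schedule.lats)):
        raise ConfigError("release box lies outside the forcing domain")
    if np.any(grid.is_land(schedule.lons, schedule.lats)):
        raise ConfigError("release box overlaps land")

    n = schedule.n
    start = schedule.dates.min()
    n_days = int(round(years * allometry.DAYS_PER_YEAR))
    dates = start + np.arange(n_days).astype("timedelta64[D]")

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng_heading = np.random.default_rng(ss.spawn(1)[0])

    lons = schedule.lons.astype(float).copy()
    lats = schedule.lats.astype(float).copy()
    status = np.full(n, ALIVE, dtype=np.int8)
    cold = np.zeros(n, dtype=np.int32)
    death_dates = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")

    rec = {name: np.full((n, n_days), np.nan) for name in TrajectorySet.FIELDS}
    alive_rec = np.zeros((n, n_days), dtype=bool)
    recorded = np.zeros((n, n_days), dtype=bool)

    exponent = allometry.vm_exponent(params.rmr_mass_exp, params.mass_exp)

    for k in range(n_days):
        date = dates[k]
        act = (status == ALIVE) & (schedule.dates <= date)
        if not np.any(act):
            continue
        idx = np.nonzero(act)[0]
        plon, plat = lons[idx], lats[idx]
        ti = forcing.loop_index(date)
        tw = bilinear(grid, forcing.sst[ti], plon, plat)
        ages = ((date - schedule.dates[idx]) / np.timedelta64(1, "D")) / allometry.DAYS_PER_YEAR
        t1, _t2 = allometry.pivotal_temperatures(ages, params)

        if mode == "active":
            h = np.empty(idx.size)
            dhdx = np.empty(idx.size)
            dhdy = np.empty(idx.size)
            ht = np.empty(idx.size)
            hf = np.empty(idx.size)
            bins = np.floor(ages / age_bin_years).astype(int)
            for b in np.unique(bins):
                sel = bins == b
                fld = habitat_field(forcing, date, (b + 0.5) * age_bin_years, params)
                h[sel] = bilinear(grid, fld.h, plon[sel], plat[sel])
                ht[sel] = bilinear(grid, fld.ht, plon[sel], plat[sel])
                hf[sel] = bilinear(grid, fld.hf, plon[sel], plat[sel])
                dhdx[sel] = bilinear(grid, fld.dhdx, plon[sel], plat[sel])
                dhdy[sel] = bilinear(grid, fld.dhdy, plon[sel], plat[sel])
            h = np.clip(h, 0.0, 1.0)
            theta = sample_headings(dhdx, dhdy, params.alpha, rng_heading, kappa_max)
            vm = params.v0 * allometry.length_at_age(ages, params) ** exponent
            us_e, us_n = swimming_velocity(vm, h, theta)
        else:
            h = ht = hf = np.full(idx.size, np.nan)
            us_e = us_n = np.zeros(idx.size)

        uc_e = bilinear(grid, forcing.u[ti], plon, plat)
        uc_n = bilinear(grid, forcing.v[ti], plon, plat)
        vg_e = uc_e + us_e
        vg_n = uc_n + us_n

        for name, val in (("lon", plon), ("lat", plat), ("tw", tw), ("h", h),
                          ("ht", ht), ("hf", hf), ("us_east", us_e),
                          ("us_north", us_n), ("uc_east", uc_e), ("uc_north", uc_n)):
            rec[name][idx, k] = val
        recorded[idx, k] = True

        # cold-exposure bookkeeping (NaN water temperature never counts cold)
        is_cold = tw < t1
        if cold_mode == "consecutive":
            cold[idx] = np.where(is_cold, cold[idx] + 1, 0)
        else:
            cold[idx] += is_cold.astype(np.int32)
        died = cold[idx] >= cold_threshold_days
        alive_rec[idx, k] = ~died
        if np.any(died):
            dd = idx[died]
            status[dd] = DEAD
            death_dates[dd] = date

        # advect survivors
        live = ~died
        ilive = idx[live]
        dlat = vg_n[live] * SECONDS_PER_DAY / M_PER_DEG
        lat_mid = plat[live] + dlat / 2.0
        dlon = vg_e[live] * SECONDS_PER_DAY / (M_PER_DEG * np.cos(lat_mid * DEG))
        nlon, nlat, exited = _candidate_step(
            grid, plon[live], plat[live], plon[live] + dlon, plat[live] + dlat, coast_mode
        )
        lons[ilive] = nlon
        lats[ilive] = nlat
        if np.any(exited):
            status[ilive[exited]] = EXITED

    return TrajectorySet(
        dates=dates, birth_dates=schedule.dates.copy(),
        alive=alive_rec, recorded=recorded, status=status, death_dates=death_dates,
        mode=mode, meta={"seed": ss.entropy, "years": years, "n": n},
        **rec,
    )
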