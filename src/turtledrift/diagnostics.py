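"""Dispersal diagnostics over trajectory sets.

Pure functions of a :class:`~turtledrift.simulation.TrajectorySet`: basin
crossing times, turtle-day density maps, cumulative mortality curves,
zonal speed decomposition, crossing-time-grouped mean latitudes and
circular heading histograms.  All of them can be re-run offline from a
saved trajectory table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import DAYS_PER_YEAR
from .simulation import DEAD, TrajectorySet

__all__ = [
    "DensityGrid",
    "pacific_crossing_time",
    "crossing_table",
    "turtle_days_density",
    "cumulative_mortality",
    "zonal_speed_decomposition",
    "grouped_mean_latitude",
    "heading_histogram",
]


def _convention_meridian(trajs: TrajectorySet, meridian: float) -> float:
    """Express the meridian in the longitude convention of the records."""
    if meridian < 0 and np.nanmax(trajs.lon) > 180.0:
        return meridian + 360.0
    return meridian


def pacific_crossing_time(lons, dates, birth_date, meridian: float):
    """Age (years) at which one track first reaches ``meridian``; None if never.

    ``lons`` must already be in a continuous longitude convention so the
    comparison is dateline-safe.
    """
    lons = np.asarray(lons, dtype=float)
    hit = np.nonzero(lons >= meridian)[0]
    if hit.size == 0:
        return None
    k = hit[0]
    return float((np.asarray(dates)[k] - birth_date) / np.timedelta64(1, "D") / DAYS_PER_YEAR)


def crossing_table(trajs: TrajectorySet, meridian: float = -140.0) -> pd.DataFrame:
    """Per-agent crossing time (years, NaN if never) and alive-at-crossing flag."""
    m = _convention_meridian(trajs, meridian)
    ages = trajs.ages_years()
    reach = trajs.recorded & (trajs.lon >= m)
    any_reach = reach.any(axis=1)
    first = np.where(any_reach, reach.argmax(axis=1), -1)
    pct = np.where(any_reach, ages[np.arange(trajs.n_agents), first], np.nan)
    alive_at = np.where(any_reach, trajs.alive[np.arange(trajs.n_agents), first], False)
    return pd.DataFrame({
        "agent": np.arange(trajs.n_agents),
        "pct_years": pct,
        "alive_at_crossing": alive_at,
    })


@dataclass(frozen=True)
class DensityGrid:
    """Turtle-day counts on a regular lon/lat binning."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    counts: np.ndarray  # (nlat_bins, nlon_bins)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def turtle_days_density(trajs: TrajectorySet, bin: float = 1.0,
                        region: tuple | None = None) -> DensityGrid:
    """Bin the daily positions of living agents into ``bin``-degree boxes.

    Each record of a living agent contributes one turtle day; records of
    dead agents (the death day itself included) are excluded.
    """
    if bin <= 0:
        raise ValueError("bin width must be positive")
    ok = trajs.recorded & trajs.alive
    lon = trajs.lon[ok]
    lat = trajs.lat[ok]
    if region is not None:
        lon0, lon1, lat0, lat1 = region
        inside = (lon >= lon0) & (lon <= lon1) & (lat >= lat0) & (lat <= lat1)
        lon, lat = lon[inside], lat[inside]
    else:
        lon0 = np.floor(lon.min() / bin) * bin if lon.size else 0.0
        lon1 = np.ceil(lon.max() / bin) * bin if lon.size else bin
        lat0 = np.floor(lat.min() / bin) * bin if lat.size else 0.0
        lat1 = np.ceil(lat.max() / bin) * bin if lat.size else bin
    lon_edges = np.arange(lon0, lon1 + bin / 2, bin)
    lat_edges = np.arange(lat0, lat1 + bin / 2, bin)
    counts, _, _ = np.histogram2d(lat, lon, bins=(lat_edges, lon_edges))
    return DensityGrid(lon_edges=lon_edges, lat_edges=lat_edges,
                       counts=counts.astype(int))


def cumulative_mortality(trajs: TrajectorySet) -> pd.Series:
    """Fraction of released agents dead by each simulated date.

    Monotone non-decreasing, in [0, 1]; the denominator is the full
    released cohort.
    """
    dead = trajs.status == DEAD
    curve = np.zeros(trajs.dates.size)
    if np.any(dead):
        day_idx = ((trajs.death_dates[dead] - trajs.dates[0])
                   / np.timedelta64(1, "D")).astype(int)
        counts = np.bincount(day_idx, minlength=trajs.dates.size)
        curve = np.cumsum(counts) / trajs.n_agents
    return pd.Series(curve, index=pd.DatetimeIndex(trajs.dates), name="fraction_dead")


def zonal_speed_decomposition(trajs: TrajectorySet, region: tuple,
                              age_min: float = 0.0):
    """Mean zonal current, swimming and ground speeds (m/s) in a region.

    Averages run over all records of living agents inside
    ``region = (lon0, lon1, lat0, lat1)`` with age >= ``age_min`` years.
    The identity mean(u_ground) = mean(u_current) + mean(u_swim) holds to
    machine precision.  Returns None when no record qualifies.
    """
    lon0, lon1, lat0, lat1 = region
    ok = (trajs.recorded & trajs.alive
          & (trajs.lon >= lon0) & (trajs.lon <= lon1)
          & (trajs.lat >= lat0) & (trajs.lat <= lat1)
          & (trajs.ages_years() >= age_min))
    if not np.any(ok):
        return None
    us = trajs.us_east[ok]
    us = np.where(np.isnan(us), 0.0, us)  # passive runs record no swimming
    uc = trajs.uc_east[ok]
    return float(np.mean(uc)), float(np.mean(us)), float(np.mean(uc + us))


def grouped_mean_latitude(trajs: TrajectorySet, crossing: pd.DataFrame,
                          group_width: float = 1.0) -> pd.DataFrame:
    """Mean latitude per day for groups of agents with similar crossing times.

    Agents are binned by crossing time into ``group_width``-year groups
    centered on integer multiples of the width (a crossing time of N
    belongs to [N - width/2, N + width/2); ties round up).  Returns a
    DataFrame indexed by date with one column per group.
    """
    pct = crossing["pct_years"].to_numpy()
    has = np.isfinite(pct)
    if not np.any(has):
        raise ValueError("no agent ever crossed the meridian")
    groups = np.full(pct.size, -1)
    groups[has] = np.floor(pct[has] / group_width + 0.5).astype(int)
    out = {}
    for g in np.unique(groups[groups >= 0]):
        members = groups == g
        masked = np.where(trajs.recorded[members], trajs.lat[members], np.nan)
        with np.errstate(invalid="ignore"):
            out[int(g)] = np.nanmean(masked, axis=0)
    return pd.DataFrame(out, index=pd.DatetimeIndex(trajs.dates))


def heading_histogram(trajs: TrajectorySet, region: tuple | None = None,
                      bin: float = 10.0):
    """Circular histogram of daily swimming headings, modal bin scaled to 100.

    Headings are degrees clockwise from North in [0, 360); zero swimming
    vectors have no heading and are excluded.  Returns (bin_edges, index)
    where ``index`` is counts * 100 / max(counts).
    """
    if 360.0 % bin:
        raise ValueError("bin must divide 360 degrees")
    ok = trajs.recorded & trajs.alive
    if region is not None:
        lon0, lon1, lat0, lat1 = region
        ok &= ((trajs.lon >= lon0) & (trajs.lon <= lon1)
               & (trajs.lat >= lat0) & (trajs.lat <= lat1))
    us_e = trajs.us_east[ok]
    us_n = trajs.us_north[ok]
    speed = np.hypot(us_e, us_n)
    moving = np.isfinite(speed) & (speed > 0)
    theta = np.degrees(np.arctan2(us_e[moving], us_n[moving])) % 360.0
    edges = np.arange(0.0, 360.0 + bin / 2, bin)
    counts, _ = np.histogram(theta, bins=edges)
    if counts.max() == 0:
        return edges, counts.astype(float)
    return edges, counts * 100.0 / counts.max()
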