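"""Regular lon/lat gridded forcing: data model, interpolation, looping, I/O.

The forcing is a finite daily series of surface currents (u, v in m/s),
sea-surface temperature (degC) and net primary production (mmol C m^-2
day^-1) on one regular longitude/latitude grid with a static land mask.
Simulations longer than the stored period loop the fields periodically.

Interpolation is bilinear in space between the four surrounding ocean cell
centers (land cells are dropped from the stencil and the weights
renormalized, so coastal values are not biased low) and linear in time
between the two bracketing daily fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS = 6_371_000.0  # m

__all__ = [
    "EARTH_RADIUS",
    "DomainError",
    "OnLandError",
    "Grid",
    "ForcingSeries",
    "interpolate_field",
    "loop_time",
    "read_forcing",
    "write_forcing",
]


class DomainError(ValueError):
    """Query position or date outside the forcing domain."""


class OnLandError(ValueError):
    """All cells of the interpolation stencil are land."""


def _as_day(t) -> np.datetime64:
    return np.datetime64(t, "D")


@dataclass(frozen=True)
class Grid:
    """Regular lon/lat grid defined by its cell centers and a land mask.

    ``lon`` and ``lat`` are strictly increasing cell-center coordinates in
    degrees with uniform spacing; ``land`` is boolean, shape (nlat, nlon),
    True over land.  Longitudes of a dateline-crossing domain must be given
    in a continuous convention (e.g. 0-360); the reader takes care of this.
    """

    lon: np.ndarray
    lat: np.ndarray
    land: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        lon = np.asarray(self.lon, dtype=float)
        lat = np.asarray(self.lat, dtype=float)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "lat", lat)
        for name, ax in (("lon", lon), ("lat", lat)):
            if ax.ndim != 1 or ax.size < 3:
                raise DomainError(f"{name} axis needs at least 3 cells")
            d = np.diff(ax)
            if np.any(d <= 0):
                raise DomainError(f"{name} axis must be strictly increasing")
            if np.ptp(d) > 1e-9 * abs(d[0]):
                raise DomainError(f"{name} spacing must be uniform")
        land = self.land
        if land is None:
            land = np.zeros((lat.size, lon.size), dtype=bool)
        land = np.asarray(land, dtype=bool)
        if land.shape != (lat.size, lon.size):
            raise DomainError("land mask shape must be (nlat, nlon)")
        object.__setattr__(self, "land", land)

    @property
    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0])

    @property
    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0])

    @property
    def ocean(self) -> np.ndarray:
        return ~self.land

    def contains(self, lon, lat) -> np.ndarray:
        """True where (lon, lat) lies inside the cell-center hull."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon[0]) & (lon <= self.lon[-1])
            & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )

    def cell_index(self, lon, lat):
        """Indices (j, i) of the cell whose center is nearest to the point."""
        i = np.clip(np.rint((np.asarray(lon) - self.lon[0]) / self.dlon), 0,
                    self.lon.size - 1).astype(int)
        j = np.clip(np.rint((np.asarray(lat) - self.lat[0]) / self.dlat), 0,
                    self.lat.size - 1).astype(int)
        return j, i

    def is_land(self, lon, lat):
        j, i = self.cell_index(lon, lat)
        return self.land[j, i]


def bilinear(grid: Grid, field2d: np.ndarray, lon, lat):
    """Masked-stencil bilinear interpolation of one 2-D field.

    Returns interpolated values; NaN where all four stencil cells are land
    (or hold NaN).  Raises :class:`DomainError` for points outside the
    cell-center hull.  Exact on fields that are linear in lon and lat over
    an all-ocean stencil.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    scalar = lon.ndim == 0 and lat.ndim == 0
    lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
    if not np.all(grid.contains(lon, lat)):
        raise DomainError("position outside grid domain")
    fx = (lon - grid.lon[0]) / grid.dlon
    fy = (lat - grid.lat[0]) / grid.dlat
    i0 = np.clip(np.floor(fx).astype(int), 0, grid.lon.size - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, grid.lat.size - 2)
    tx = fx - i0
    ty = fy - j0

    vals = np.zeros(lon.shape)
    wsum = np.zeros(lon.shape)
    for dj, di, w in (
        (0, 0, (1 - tx) * (1 - ty)),
        (0, 1, tx * (1 - ty)),
        (1, 0, (1 - tx) * ty),
        (1, 1, tx * ty),
    ):
        f = field2d[j0 + dj, i0 + di]
        ok = grid.ocean[j0 + dj, i0 + di] & np.isfinite(f)
        w = np.where(ok, w, 0.0)
        vals += w * np.where(ok, f, 0.0)
        wsum += w
    out = np.where(wsum > 0, vals / np.where(wsum > 0, wsum, 1.0), np.nan)
    return float(out[0]) if scalar else out


@dataclass
class ForcingSeries:
    """Daily gridded forcing over one finite, loopable period.

    ``times`` is a contiguous daily axis (datetime64[D]); the four field
    arrays have shape (ntime, nlat, nlon).  ``period_length`` (days)
    defaults to the full stored span and controls periodic looping.
    """

    grid: Grid
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    sst: np.ndarray
    npp: np.ndarray
    period_length: int = 0
    attrs: dict = field(default_factory=dict)

    VARS = ("u", "v", "sst", "npp")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[D]")
        nt = self.times.size
        if nt < 1 or np.any(np.diff(self.times) != np.timedelta64(1, "D")):
            raise DomainError("times must be a contiguous daily axis")
        shape = (nt, self.grid.lat.size, self.grid.lon.size)
        for name in self.VARS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise DomainError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        if self.period_length <= 0:
            self.period_length = nt
        ocean3 = self.grid.ocean[None, :, :]
        if np.any(self.npp[np.broadcast_to(ocean3, shape)] < -1e-12):
            raise DomainError("npp must be non-negative over ocean")
        for name in ("u", "v", "sst"):
            if not np.all(np.isfinite(getattr(self, name)[np.broadcast_to(ocean3, shape)])):
                raise DomainError(f"{name} must be finite over ocean cells")

    def field(self, name: str) -> np.ndarray:
        if name not in self.VARS:
            raise KeyError(f"unknown variable {name!r}")
        return getattr(self, name)

    def loop_index(self, t) -> int:
        """Index into the stored time axis of the looped timestamp."""
        tl = loop_time(t, self)
        k = int((tl - self.times[0]) / np.timedelta64(1, "D"))
        if not 0 <= k < self.times.size:
            raise DomainError("looped date falls outside the stored time axis")
        return k


def loop_time(t, series: ForcingSeries) -> np.datetime64:
    """Map ``t`` modulo the forcing period onto the stored time axis.

    Identity for timestamps already inside the period.
    """
    if series.period_length <= 0:
        raise DomainError("period_length must be positive")
    t0 = series.times[0]
    off = int((_as_day(t) - t0) / np.timedelta64(1, "D")) % series.period_length
    return t0 + np.timedelta64(off, "D")


def interpolate_field(series: ForcingSeries, variable: str, lon, lat, t):
    """Space-time interpolation of one forcing variable at a point.

    Bilinear between the four surrounding ocean cell centers, linear in
    time between the two bracketing daily fields (looping applied first).
    Raises :class:`OnLandError` when the whole stencil is land.
    """
    data = series.field(variable)
    t = _as_day(t)
    tl = loop_time(t, series)
    k0 = int((tl - series.times[0]) / np.timedelta64(1, "D"))
    # daily axis: tl always falls exactly on a stored day, weight w = 0
    v0 = bilinear(series.grid, data[k0], lon, lat)
    if np.any(np.isnan(v0)):
        raise OnLandError("all stencil cells are land")
    return v0


def to_dataset(series: ForcingSeries) -> xr.Dataset:
    """Represent the forcing as a CF-style xarray Dataset (land as NaN)."""
    mask3 = np.broadcast_to(series.grid.land, series.u.shape)
    data = {
        name: (("time", "lat", "lon"), np.where(mask3, np.nan, series.field(var)))
        for name, var in (("uo", "u"), ("vo", "v"), ("sst", "sst"), ("npp", "npp"))
    }
    ds = xr.Dataset(
        data,
        coords={
            "time": series.times.astype("datetime64[ns]"),
            "lat": series.grid.lat,
            "lon": series.grid.lon,
        },
        attrs={"period_length": series.period_length, **series.attrs},
    )
    ds["uo"].attrs["units"] = "m s-1"
    ds["vo"].attrs["units"] = "m s-1"
    ds["sst"].attrs["units"] = "degC"
    ds["npp"].attrs["units"] = "mmol C m-2 day-1"
    return ds


def write_forcing(series: ForcingSeries, path) -> None:
    """Write the forcing to netCDF (classic format, scipy backend)."""
    to_dataset(series).to_netcdf(path, engine="scipy")


_DEFAULT_NAMES = {
    "u": ("uo", "u"),
    "v": ("vo", "v"),
    "sst": ("thetao", "sst", "tos"),
    "npp": ("npp", "pp"),
}


def _pick(ds: xr.Dataset, candidates) -> str:
    for name in candidates:
        if name in ds:
            return name
    raise KeyError(f"none of {candidates} found in dataset (has {list(ds.data_vars)})")


def read_forcing(path, names: dict | None = None, period_length: int = 0) -> ForcingSeries:
    """Read gridded forcing from a CF-style netCDF file.

    ``names`` may map any of u/v/sst/npp to the variable name used in the
    file; common defaults (uo, vo, thetao/sst, npp) are tried otherwise.
    The land mask is inferred from cells that are NaN in every variable.
    Longitudes of a dateline-crossing domain stored in [-180, 180] are
    shifted to a continuous 0-360 convention.
    """
    ds = xr.open_dataset(path, engine="scipy")
    lookup = dict(_DEFAULT_NAMES)
    if names:
        lookup.update({k: (v,) for k, v in names.items()})
    lon_name = _pick(ds.coords, ("lon", "longitude", "x"))
    lat_name = _pick(ds.coords, ("lat", "latitude", "y"))
    time_name = _pick(ds.coords, ("time",))
    lons = np.asarray(ds[lon_name].values, dtype=float)
    if np.any(np.diff(lons) < 0):  # dateline jump: move to 0-360 and re-sort
        lons = np.where(lons < 0, lons + 360.0, lons)
        order = np.argsort(lons)
        ds = ds.isel({lon_name: order})
        lons = lons[order]
    fields = {}
    for var, candidates in lookup.items():
        da = ds[_pick(ds, candidates)].transpose(time_name, lat_name, lon_name)
        fields[var] = np.asarray(da.values, dtype=float)
    land = np.all([np.all(np.isnan(f), axis=0) for f in fields.values()], axis=0)
    grid = Grid(lons, np.asarray(ds[lat_name].values, dtype=float), land)
    for var in fields:
        fields[var] = np.where(np.isnan(fields[var]), 0.0, fields[var])
    times = pd.to_datetime(ds[time_name].values).values.astype("datetime64[D]")
    plen = period_length or int(ds.attrs.get("period_length", 0))
    return ForcingSeries(grid=grid, times=times, period_length=plen, **fields)
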