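"""Habitat suitability index h = hF * hT and its spatial gradient.

The thermal index hT is 1 inside the thermal preferendum and falls off
along Gaussian flanks scaled by the pivotal temperatures; the feeding
index hF is the local prey proxy (NPP) divided by the age-dependent food
requirement, capped at 1.  Gradients are per meter, computed at cell
centers by centered finite differences with the spherical metric
(dx = R*cos(lat)*dlon_rad, dy = R*dlat_rad); one-sided differences are
used at domain edges and next to land so coastlines do not fabricate
spurious shoreward gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .allometry import food_threshold, pivotal_temperatures
from .grids import EARTH_RADIUS, DomainError, ForcingSeries, Grid
from .params import ConfigError, SpeciesParams

__all__ = [
    "HabitatField",
    "thermal_suitability",
    "feeding_suitability",
    "total_suitability",
    "habitat_field",
    "masked_gradient",
    "median_gradient_magnitude",
    "calibrate_alpha",
]

log = logging.getLogger(__name__)
DEG = np.pi / 180.0


def thermal_suitability(tw, t1, t2, t3=None, t4=None):
    """Thermal habitat index in [0, 1].

    1 on the preferendum [t2, t3]; exp(-2*((tw-t2)/(t2-t1))**2) below t2;
    exp(-2*((tw-t3)/(t4-t3))**2) above t3.  When t3/t4 are unset the index
    is 1 for all tw >= t2 (no unsuitably warm water).  Continuous at the
    junctions, and still positive (exp(-2)) at the critical temperature t1
    so near-critical individuals keep a usable escape gradient.
    """
    tw = np.asarray(tw, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 >= t2):
        raise ConfigError("pivotal temperatures must satisfy T1 < T2")
    if (t3 is None) != (t4 is None):
        raise ConfigError("T3 and T4 must be provided together")
    h = np.ones(np.broadcast_shapes(tw.shape, t1.shape, t2.shape))
    cold = tw < t2
    h = np.where(cold, np.exp(-2.0 * ((tw - t2) / (t2 - t1)) ** 2), h)
    if t3 is not None:
        t3 = np.asarray(t3, dtype=float)
        t4 = np.asarray(t4, dtype=float)
        if np.any(t3 >= t4):
            raise ConfigError("pivotal temperatures must satisfy T3 < T4")
        warm = tw > t3
        h = np.where(warm, np.exp(-2.0 * ((tw - t3) / (t4 - t3)) ** 2), h)
    return h if h.ndim else float(h)


def feeding_suitability(npp, a, params: SpeciesParams = SpeciesParams()):
    """Feeding habitat index min(1, NPP / F(a)) in [0, 1].

    Negative NPP (cloud or retrieval artifacts in satellite products) is
    clamped to zero with a logged warning.
    """
    npp = np.asarray(npp, dtype=float)
    if np.any(npp < 0):
        log.warning("negative NPP clamped to 0 (%d values)", int(np.sum(npp < 0)))
        npp = np.maximum(npp, 0.0)
    thr = np.asarray(food_threshold(a, params), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hf = np.where(thr > 0, np.minimum(1.0, npp / np.where(thr > 0, thr, 1.0)), 1.0)
    return hf if hf.ndim else float(hf)


def total_suitability(hf, ht):
    """Product habitat index h = hF * hT, in [0, 1]."""
    h = np.asarray(hf, dtype=float) * np.asarray(ht, dtype=float)
    return h if h.ndim else float(h)


def masked_gradient(field2d: np.ndarray, grid: Grid):
    """Per-meter gradient (d/dx eastward, d/dy northward) at cell centers.

    Centered differences where both neighbors are ocean, one-sided toward
    the available side next to land or the domain edge, zero where no
    ocean neighbor exists.  Exact on fields linear in the metric
    coordinates away from boundaries.
    """
    f = np.asarray(field2d, dtype=float)
    ocean = grid.ocean
    dy = EARTH_RADIUS * grid.dlat * DEG
    dx = EARTH_RADIUS * np.cos(grid.lat * DEG)[:, None] * grid.dlon * DEG

    def axis_gradient(delta, axis):
        prev = np.roll(f, 1, axis=axis)
        nxt = np.roll(f, -1, axis=axis)
        ok_prev = np.roll(ocean, 1, axis=axis)
        ok_next = np.roll(ocean, -1, axis=axis)
        # roll wraps around: invalidate the wrapped edge rows/columns
        edge = [slice(None)] * 2
        edge[axis] = 0
        ok_prev[tuple(edge)] = False
        edge[axis] = -1
        ok_next[tuple(edge)] = False
        centered = (nxt - prev) / (2.0 * delta)
        fwd = (nxt - f) / delta
        bwd = (f - prev) / delta
        g = np.where(ok_prev & ok_next, centered,
                     np.where(ok_next, fwd, np.where(ok_prev, bwd, 0.0)))
        return np.where(ocean, g, np.nan)

    dfdx = axis_gradient(dx, axis=1)
    dfdy = axis_gradient(dy, axis=0)
    return dfdx, dfdy


@dataclass(frozen=True)
class HabitatField:
    """Habitat index and gradient on the forcing grid for one date and age."""

    grid: Grid
    date: np.datetime64
    age: float
    h: np.ndarray
    ht: np.ndarray
    hf: np.ndarray
    dhdx: np.ndarray
    dhdy: np.ndarray


def habitat_field(
    forcing: ForcingSeries,
    date,
    a: float,
    params: SpeciesParams = SpeciesParams(),
) -> HabitatField:
    """Evaluate h = hF*hT and its gradient for age ``a`` on one (looped) day."""
    k = forcing.loop_index(date)
    t1, t2 = pivotal_temperatures(a, params)
    ht = thermal_suitability(forcing.sst[k], t1, t2, params.T3, params.T4)
    hf = feeding_suitability(forcing.npp[k], a, params)
    h = total_suitability(hf, ht)
    land = forcing.grid.land
    h = np.where(land, np.nan, h)
    ht = np.where(land, np.nan, ht)
    hf = np.where(land, np.nan, hf)
    dhdx, dhdy = masked_gradient(np.where(land, 0.0, h), forcing.grid)
    return HabitatField(grid=forcing.grid, date=forcing.times[k], age=float(a),
                        h=h, ht=ht, hf=hf, dhdx=dhdx, dhdy=dhdy)


def habitat_to_dataset(fields):
    """Stack habitat fields (one date, one age each) into an xarray Dataset.

    Useful for writing daily h/hT/hF/gradient rasters to netCDF for
    inspection, e.g. ``habitat_to_dataset(fields).to_netcdf(path,
    engine="scipy")``.
    """
    import xarray as xr

    fields = list(fields)
    if not fields:
        raise DomainError("no habitat fields supplied")
    grid = fields[0].grid
    data = {
        name: (("time", "lat", "lon"),
               np.stack([getattr(f, name) for f in fields]))
        for name in ("h", "ht", "hf", "dhdx", "dhdy")
    }
    return xr.Dataset(
        data,
        coords={
            "time": np.array([f.date for f in fields], dtype="datetime64[ns]"),
            "lat": grid.lat,
            "lon": grid.lon,
            "age": ("time", [f.age for f in fields]),
        },
    )


def _interior_mask(grid: Grid) -> np.ndarray:
    """Ocean cells whose four neighbors are ocean and not on the domain edge."""
    ocean = grid.ocean
    m = np.zeros_like(ocean)
    m[1:-1, 1:-1] = (
        ocean[1:-1, 1:-1]
        & ocean[:-2, 1:-1] & ocean[2:, 1:-1]
        & ocean[1:-1, :-2] & ocean[1:-1, 2:]
    )
    return m


def median_gradient_magnitude(fields) -> float:
    """Median of |grad h| (1/m) over ocean interior cells of the given fields.

    The auto-calibration of the heading-concentration scale alpha uses
    this median: alpha = kappa_target / median.
    """
    mags = []
    for fld in fields:
        m = _interior_mask(fld.grid)
        if np.any(m):
            mags.append(np.hypot(fld.dhdx[m], fld.dhdy[m]))
    if not mags:
        raise DomainError("no ocean interior cells in the supplied fields")
    return float(np.median(np.concatenate(mags)))


def calibrate_alpha(median_grad: float, kappa_target: float = 4.0) -> float:
    """Gradient-to-concentration scale alpha (m) from a target kappa.

    Chosen so that a gradient at the median magnitude yields a heading
    concentration ``kappa_target`` — i.e. clearly directed movement
    (deviations beyond 90 degrees essentially vanish at kappa = 4)
    whenever the habitat gradient is above its median.
    """
    if median_grad <= 0:
        raise DomainError("median gradient magnitude must be positive")
    return kappa_target / median_grad
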