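"""Synthetic forcing: an idealized subtropical-gyre test basin.

The generator builds a closed, near-divergence-free circulation from an
analytic streamfunction: an eastward mid-latitude jet, a weaker eastward
low-latitude countercurrent, a broad westward return flow between them
(its amplitude set internally so the basin-integrated zonal transport
closes), and basin-scale meridional limbs that recirculate the flow along
the western and eastern boundaries.  A travelling meander wave superposed
on the low-latitude flank stirs particles across the mean streamlines, so
passive drifters released in the tropics eventually reach the cold north
of the basin, as they do in the real ocean.

SST decreases poleward through a smooth mid-latitude front with a seasonal
cycle whose amplitude grows across the front (the profile stays monotone
in latitude on every day of the year).  NPP decays from west to east, with
an elevated, seasonally pulsing band north of the jet (the productive
transition-zone analogue) and a productive strip along the eastern
boundary.

Velocities are obtained by *spherical* centered finite differences of the
streamfunction sampled at cell centers, which makes the discrete spherical
divergence vanish to rounding error on interior cells.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import erf

from .grids import EARTH_RADIUS, Grid, ForcingSeries, DomainError

__all__ = ["SyntheticForcingConfig", "make_synthetic_forcing"]

DEG = np.pi / 180.0


@dataclass(frozen=True)
class SyntheticForcingConfig:
    """Parameters of the synthetic basin (degrees, m/s, degC, NPP units)."""

    # domain
    lon_min: float = 120.0
    lon_max: float = 280.0
    lat_min: float = 0.0
    lat_max: float = 50.0
    step: float = 1.0
    # circulation
    jet_lat: float = 35.0
    jet_speed: float = 0.4
    jet_width: float = 6.0
    cc_lat: float = 6.0
    cc_speed: float = 0.3
    cc_width: float = 2.5
    return_lat: float = 17.0
    return_width: float = 7.0
    gyre_strength: float = 0.12  # meander-wave velocity scale, m/s
    wave_period: float = 73.0  # days
    wave_lat: float = 15.0
    wave_width: float = 6.0
    wave_number: int = 3  # zonal wavelengths across the basin
    # SST
    sst_equator: float = 28.0
    sst_pole: float = 8.0
    sst_front_lat: float = 35.0
    sst_front_width: float = 8.0
    sst_seasonal_amp: float = 9.0
    sst_seasonal_phase: float = 235.0  # day of year of warmest SST
    # NPP: a low-productivity gyre core (floor), a rich transition-zone
    # band north of the jet whose level decays from west to east, and a
    # productive eastern-boundary upwelling strip
    npp_floor: float = 8.0
    npp_floor_tilt: float = 0.02  # fractional increase of the floor per degree poleward
    npp_west: float = 80.0
    npp_east: float = 20.0
    npp_decay_scale: float = 50.0  # degrees of longitude
    npp_east_boundary: float = 60.0
    npp_east_boundary_width: float = 4.0
    npp_east_boundary_lat_min: float = 25.0  # upwelling strip fades south of this
    npp_band_lat: float = 40.0
    npp_band_width: float = 7.0
    npp_seasonal_amp: float = 0.3
    npp_seasonal_phase: float = 200.0
    # coasts: make the westernmost and easternmost columns land
    boundary_land: bool = True
    # time
    period_days: int = 365
    start_date: str = "2000-01-01"
    seed: int = 0

    def __post_init__(self):
        for name in ("jet_speed", "cc_speed", "gyre_strength"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if not self.sst_equator > self.sst_pole:
            raise DomainError("sst_equator must exceed sst_pole")
        for name in ("npp_floor", "npp_west", "npp_east", "npp_east_boundary"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if (self.lon_max - self.lon_min) / self.step < 2 or (
            self.lat_max - self.lat_min
        ) / self.step < 2:
            raise DomainError("domain must span at least 3 cells per axis")
        if self.sst_seasonal_amp >= self.sst_equator - self.sst_pole:
            raise DomainError("seasonal amplitude must stay below the pole-equator contrast")


def _gauss(x, mu, w):
    return np.exp(-0.5 * ((x - mu) / w) ** 2)


def _gauss_integral(mu, w, a, b):
    """Integral of the unit Gaussian bump between latitudes a and b (degrees)."""
    s = w * np.sqrt(np.pi / 2.0)
    return s * (erf((b - mu) / (np.sqrt(2) * w)) - erf((a - mu) / (np.sqrt(2) * w)))


def make_synthetic_forcing(config: SyntheticForcingConfig = SyntheticForcingConfig()) -> ForcingSeries:
    """Generate a :class:`ForcingSeries` for the synthetic basin.

    Deterministic: the same config (seed included) always yields the same
    fields bit for bit.
    """
    c = config
    lon = np.arange(c.lon_min, c.lon_max + c.step / 2, c.step)
    lat = np.arange(c.lat_min, c.lat_max + c.step / 2, c.step)
    land = np.zeros((lat.size, lon.size), dtype=bool)
    if c.boundary_land:
        land[:, 0] = land[:, -1] = True
    grid = Grid(lon, lat, land)
    nt = int(c.period_days)
    t0 = np.datetime64(c.start_date, "D")
    times = t0 + np.arange(nt)

    lam = lon[None, :]  # (1, nlon) degrees
    phi = lat[:, None]  # (nlat, 1) degrees
    xhat = (lam - lon[0]) / (lon[-1] - lon[0])

    # --- streamfunction -------------------------------------------------
    # Zonal-mean profile: jet + countercurrent - return flow.  The three
    # Gaussian amplitudes solve a small linear system so that (a) the
    # total profile equals the configured peak speeds exactly at the jet
    # and countercurrent latitudes despite overlapping tails and (b) the
    # meridionally integrated transport is zero, which closes the
    # streamfunction on the northern boundary.
    bumps = (
        (c.jet_lat, c.jet_width),
        (c.cc_lat, c.cc_width),
        (c.return_lat, c.return_width),
    )
    system = np.array(
        [[_gauss(lat0, mu, w) for mu, w in bumps] for lat0 in (c.jet_lat, c.cc_lat)]
        + [[_gauss_integral(mu, w, c.lat_min, c.lat_max) for mu, w in bumps]]
    )
    amp = np.linalg.solve(system, np.array([c.jet_speed, c.cc_speed, 0.0]))

    def s_psi(phi_deg):
        """-R * integral of the zonal profile from lat_min (m^2/s)."""
        parts = sum(
            a * _gauss_integral(mu, w, c.lat_min, phi_deg)
            for a, (mu, w) in zip(amp, bumps)
        )
        return -EARTH_RADIUS * DEG * parts

    psi_gyre = np.sin(np.pi * xhat) * s_psi(phi)  # (nlat, nlon)
    wave_env = (
        c.gyre_strength
        * EARTH_RADIUS * DEG * c.wave_width
        * np.sin(np.pi * xhat)
        * _gauss(phi, c.wave_lat, c.wave_width)
    )

    day = np.arange(nt, dtype=float)
    wave_phase = 2.0 * np.pi * (c.wave_number * xhat[None, :, :] - day[:, None, None] / c.wave_period)
    psi = psi_gyre[None, :, :] + wave_env[None, :, :] * np.cos(wave_phase)

    # --- velocities by spherical centered differences -------------------
    dphi = c.step * DEG
    dlam = c.step * DEG
    cosphi = np.cos(phi * DEG)[None, :, :]

    u = np.empty_like(psi)
    u[:, 1:-1, :] = -(psi[:, 2:, :] - psi[:, :-2, :]) / (2 * EARTH_RADIUS * dphi)
    u[:, 0, :] = -(psi[:, 1, :] - psi[:, 0, :]) / (EARTH_RADIUS * dphi)
    u[:, -1, :] = -(psi[:, -1, :] - psi[:, -2, :]) / (EARTH_RADIUS * dphi)

    v = np.empty_like(psi)
    v[:, :, 1:-1] = (psi[:, :, 2:] - psi[:, :, :-2]) / (2 * EARTH_RADIUS * dlam)
    v[:, :, 0] = (psi[:, :, 1] - psi[:, :, 0]) / (EARTH_RADIUS * dlam)
    v[:, :, -1] = (psi[:, :, -1] - psi[:, :, -2]) / (EARTH_RADIUS * dlam)
    v /= cosphi

    # --- SST -------------------------------------------------------------
    front = 0.5 * (1.0 + np.tanh((phi - c.sst_front_lat) / c.sst_front_width))
    season = np.cos(2.0 * np.pi * (day - c.sst_seasonal_phase) / c.period_days)
    sst = (
        c.sst_equator
        - (c.sst_equator - c.sst_pole) * front[None, :, :]
        + c.sst_seasonal_amp * front[None, :, :] * season[:, None, None]
    )
    sst = np.ascontiguousarray(np.broadcast_to(sst, psi.shape))

    # --- NPP -------------------------------------------------------------
    west_decay = np.exp(-(lam - lon[0]) / c.npp_decay_scale)
    zonal = c.npp_east + (c.npp_west - c.npp_east) * west_decay
    band = _gauss(phi, c.npp_band_lat, c.npp_band_width)
    npp_season = 1.0 + c.npp_seasonal_amp * np.cos(
        2.0 * np.pi * (day - c.npp_seasonal_phase) / c.period_days
    )
    lat_taper = 1.0 / (1.0 + np.exp(-(phi - c.npp_east_boundary_lat_min) / 3.0))
    east_strip = (
        c.npp_east_boundary
        * _gauss(lam, lon[-1], c.npp_east_boundary_width)
        * lat_taper
    )
    floor = c.npp_floor * (1.0 + c.npp_floor_tilt * (phi - c.lat_min))
    npp = (
        floor[None, :, :]
        + ((zonal - c.npp_floor) * band)[None, :, :] * npp_season[:, None, None]
        + east_strip[None, :, :]
    )

    return ForcingSeries(
        grid=grid,
        times=times,
        u=u,
        v=v,
        sst=sst,
        npp=np.maximum(npp, 0.0),
        period_length=nt,
        attrs={"synthetic": 1, **{f"cfg_{k}": v for k, v in asdict(c).items() if not isinstance(v, str)}},
    )
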