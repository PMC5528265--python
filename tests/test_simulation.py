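"""Release scheduling, stepping, mortality bookkeeping and whole-run behavior."""

import numpy as np
import pytest

from turtledrift.grids import bilinear
from turtledrift.params import ConfigError
from turtledrift.simulation import (
    ALIVE,
    DEAD,
    EXITED,
    M_PER_DEG,
    ReleaseSchedule,
    TrajectorySet,
    TurtleState,
    build_release_schedule,
    run_simulation,
    step_position,
    update_cold_mortality,
)
from turtledrift import allometry as al

from conftest import make_uniform_forcing

DEG = np.pi / 180.0


def stationary_schedule(n, lon, lat, date="2000-01-01"):
    d = np.full(n, np.datetime64(date, "D"))
    return ReleaseSchedule(dates=d, lons=np.full(n, float(lon)),
                           lats=np.full(n, float(lat)),
                           box_center=(lon, lat), box_width=0.0)


class TestReleaseSchedule:
    def test_cohort_size_and_window(self):
        sch = build_release_schedule(
            5000, ("2000-06-01", "2000-11-30"), "2000-09-15", 30.0,
            (137.0, 13.5), 0.25, seed=3)
        assert sch.n == 5000
        assert sch.dates.min() >= np.datetime64("2000-06-01")
        assert sch.dates.max() <= np.datetime64("2000-11-30")

    def test_peak_of_daily_counts(self):
        sch = build_release_schedule(
            5000, ("2000-06-01", "2000-11-30"), "2000-09-15", 30.0,
            (137.0, 13.5), 0.25, seed=3)
        days, counts = np.unique(sch.dates, return_counts=True)
        mode_day = days[np.argmax(counts)]
        assert abs((mode_day - np.datetime64("2000-09-15"))
                   / np.timedelta64(1, "D")) <= 5

    def test_positions_inside_box(self):
        sch = build_release_schedule(
            1000, ("2000-06-01", "2000-11-30"), "2000-09-15", 30.0,
            (137.0, 13.5), 0.25, seed=3)
        assert np.all(np.abs(sch.lons - 137.0) <= 0.125)
        assert np.all(np.abs(sch.lats - 13.5) <= 0.125)

    def test_deterministic_given_seed(self):
        args = (200, ("2000-06-01", "2000-11-30"), "2000-09-15", 30.0,
                (137.0, 13.5), 0.25)
        a = build_release_schedule(*args, seed=9)
        b = build_release_schedule(*args, seed=9)
        assert np.array_equal(a.dates, b.dates)
        assert np.array_equal(a.lons, b.lons)

    def test_invalid_window(self):
        with pytest.raises(ConfigError):
            build_release_schedule(10, ("2000-11-30", "2000-06-01"),
                                   "2000-09-15", 30.0, (0, 0))


class TestStepPosition:
    def state(self, lon=10.0, lat=0.0):
        return TurtleState(id=0, lon=lon, lat=lat,
                           birth_date=np.datetime64("2000-01-01"))

    def test_zero_velocity_is_identity(self):
        assert step_position(self.state(), (0.0, 0.0)) == (10.0, 0.0)

    def test_one_ms_east_at_equator(self):
        lon, lat = step_position(self.state(), (1.0, 0.0))
        assert lon - 10.0 == pytest.approx(0.7770, abs=1e-4)
        assert lat == 0.0

    @pytest.mark.parametrize("lat0", [-40.0, 0.0, 55.0])
    def test_one_ms_north_latitude_independent(self, lat0):
        _, lat = step_position(self.state(lat=lat0), (0.0, 1.0))
        assert lat - lat0 == pytest.approx(0.7770, abs=1e-4)

    def test_dead_agent_never_stepped(self):
        s = self.state()
        s.alive = False
        with pytest.raises(ValueError):
            step_position(s, (0.0, 0.0))


class TestColdMortality:
    def state(self):
        return TurtleState(id=0, lon=0, lat=0,
                           birth_date=np.datetime64("2000-01-01"))

    def test_ten_consecutive_cold_days_kill(self):
        s = self.state()
        for day in range(10):
            s.age_days = day
            s = update_cold_mortality(s, tw=5.0, t1=10.0)
        assert not s.alive
        assert s.death_date == np.datetime64("2000-01-10")

    def test_warm_day_resets_the_spell(self):
        s = self.state()
        for _ in range(9):
            s = update_cold_mortality(s, 5.0, 10.0)
        s = update_cold_mortality(s, 15.0, 10.0)
        for _ in range(9):
            s = update_cold_mortality(s, 5.0, 10.0)
        assert s.alive and s.cold_days == 9

    def test_cumulative_mode_does_not_reset(self):
        s = self.state()
        for _ in range(9):
            s = update_cold_mortality(s, 5.0, 10.0, mode="cumulative")
        s = update_cold_mortality(s, 15.0, 10.0, mode="cumulative")
        s = update_cold_mortality(s, 5.0, 10.0, mode="cumulative")
        assert not s.alive

    def test_always_warm_never_counts(self):
        s = self.state()
        for _ in range(50):
            s = update_cold_mortality(s, 25.0, 10.0)
        assert s.alive and s.cold_days == 0

    def test_run_level_death_on_day_ten(self):
        f = make_uniform_forcing(days=20, sst=0.0)  # lethally cold everywhere
        sch = stationary_schedule(4, 3.0, 2.0)
        tr = run_simulation(f, sch, mode="passive", years=1, seed=0)
        assert np.all(tr.status == DEAD)
        assert np.all(tr.death_dates == np.datetime64("2000-01-10"))
        assert tr.recorded.sum(axis=1).tolist() == [10] * 4
        assert not tr.alive[:, 9].any() and tr.alive[:, 8].all()


class TestRunSimulation:
    def test_conservation_and_constraints(self, small_synth_forcing):
        sch = build_release_schedule(
            40, ("2000-06-01", "2000-11-30"), "2000-09-15", 30.0,
            (137.0, 13.5), 0.25, seed=1)
        tr = run_simulation(small_synth_forcing, sch, mode="active",
                           years=3, seed=4)
        counts = {s: int(np.sum(tr.status == s)) for s in (ALIVE, DEAD, EXITED)}
        assert sum(counts.values()) == 40
        # no recorded position on land, no swim speed above the age ceiling
        rec = tr.recorded
        grid = small_synth_forcing.grid
        assert not grid.is_land(tr.lon[rec], tr.lat[rec]).any()
        vmax = al.speed_at_age(np.maximum(tr.ages_years(), 0.0))
        speed = np.hypot(tr.us_east, tr.us_north)
        assert np.all(speed[rec] <= vmax[rec] + 1e-12)
        # ground = current + swimming holds for every record by construction
        assert np.isfinite(tr.uc_east[rec]).all()

    def test_seed_determinism(self, small_synth_forcing):
        sch = build_release_schedule(
            20, ("2000-06-01", "2000-11-30"), "2000-09-15", 30.0,
            (137.0, 13.5), 0.25, seed=1)
        a = run_simulation(small_synth_forcing, sch, mode="active", years=2, seed=8)
        b = run_simulation(small_synth_forcing, sch, mode="active", years=2, seed=8)
        for name in TrajectorySet.FIELDS:
            assert np.array_equal(getattr(a, name), getattr(b, name), equal_nan=True)
        assert np.array_equal(a.status, b.status)

    def test_release_outside_domain_rejected(self, small_synth_forcing):
        sch = stationary_schedule(5, 300.0, 10.0)
        with pytest.raises(ConfigError):
            run_simulation(small_synth_forcing, sch, years=1)

    def test_saturated_habitat_reproduces_passive(self):
        # warm water and over-saturated food: h = 1, so active swimming
        # vanishes and the trajectories collapse onto pure drift
        f = make_uniform_forcing(nlon=30, nlat=20, days=40, sst=28.0, npp=1e4,
                                 u=0.05, v=0.02)
        sch = stationary_schedule(8, 5.0, 3.0)
        active = run_simulation(f, sch, mode="active", years=2, seed=3)
        passive = run_simulation(f, sch, mode="passive", years=2, seed=3)
        assert np.array_equal(active.lon, passive.lon, equal_nan=True)
        assert np.array_equal(active.lat, passive.lat, equal_nan=True)
        assert np.array_equal(active.status, passive.status)

    def test_hostile_flat_habitat_is_unbiased_random_walk(self):
        # no food anywhere (h = 0, zero gradient), warm water, no currents:
        # uniform headings at full sustainable speed, no net drift
        f = make_uniform_forcing(nlon=81, nlat=81, days=10, sst=28.0, npp=0.0)
        n = 300
        sch = stationary_schedule(n, 40.0, 40.0)
        tr = run_simulation(f, sch, mode="active", years=1, seed=6)
        k = 100
        dlon = tr.lon[:, k] - tr.lon[:, 0]
        dlat = tr.lat[:, k] - tr.lat[:, 0]
        assert abs(np.mean(dlon)) < 1.5 and abs(np.mean(dlat)) < 1.5
        # each daily swim displacement has the full sustainable speed
        speed = np.hypot(tr.us_east[:, :k], tr.us_north[:, :k])
        vm = al.speed_at_age(tr.ages_years()[:, :k])
        np.testing.assert_allclose(speed, vm, rtol=1e-12)

    def test_passive_matches_independent_advection_oracle(self, small_synth_forcing):
        sch = build_release_schedule(
            15, ("2000-06-01", "2000-11-30"), "2000-09-15", 30.0,
            (137.0, 13.5), 0.25, seed=2)
        tr = run_simulation(small_synth_forcing, sch, mode="passive",
                           years=2, seed=5, cold_threshold_days=10**6)
        f = small_synth_forcing
        grid = f.grid
        lon = sch.lons.copy()
        lat = sch.lats.copy()
        frozen = np.zeros(lon.size, dtype=bool)
        start = sch.dates.min()
        for k in range(tr.dates.size):
            date = start + np.timedelta64(k, "D")
            act = (~frozen) & (sch.dates <= date)
            if np.any(act):
                np.testing.assert_array_equal(lon[act], tr.lon[act, k])
                np.testing.assert_array_equal(lat[act], tr.lat[act, k])
                ti = f.loop_index(date)
                ue = bilinear(grid, f.u[ti], lon[act], lat[act])
                vn = bilinear(grid, f.v[ti], lon[act], lat[act])
                dlat = vn * 86400.0 / M_PER_DEG
                latm = lat[act] + dlat / 2.0
                dlon = ue * 86400.0 / (M_PER_DEG * np.cos(latm * DEG))
                lo, la = lon[act] + dlon, lat[act] + dlat
                inside = grid.contains(lo, la)
                sea = inside & ~grid.is_land(np.where(inside, lo, lon[act]),
                                             np.where(inside, la, lat[act]))
                # free slip: zonal-only, then meridional-only, else stay
                zon_ok = ~sea & inside & ~grid.is_land(lo, lat[act])
                mer_ok = ~sea & inside & ~zon_ok & ~grid.is_land(lon[act], la)
                new_lon = np.where(sea | zon_ok, lo, lon[act])
                new_lat = np.where(sea | mer_ok, la, lat[act])
                idx = np.nonzero(act)[0]
                frozen[idx[~inside]] = True
                lon[idx], lat[idx] = new_lon, new_lat

    def test_trajectory_table_roundtrip(self):
        f = make_uniform_forcing(nlon=30, nlat=20, days=40, sst=28.0, npp=1e4,
                                 u=0.03, v=0.01)
        sch = stationary_schedule(5, 5.0, 3.0)
        tr = run_simulation(f, sch, mode="active", years=1, seed=3)
        back = TrajectorySet.from_dataframe(tr.to_dataframe())
        assert np.array_equal(back.recorded, tr.recorded)
        assert np.array_equal(back.alive, tr.alive)
        rec = tr.recorded
        for name in TrajectorySet.FIELDS:
            np.testing.assert_allclose(getattr(back, name)[rec],
                                       getattr(tr, name)[rec], equal_nan=True)
        assert np.array_equal(back.birth_dates, tr.birth_dates)

    def test_netcdf_writer(self, tmp_path):
        import xarray as xr

        f = make_uniform_forcing(days=10, sst=28.0, npp=1e3)
        sch = stationary_schedule(3, 3.0, 2.0)
        tr = run_simulation(f, sch, mode="active", years=1, seed=2)
        path = tmp_path / "traj.nc"
        tr.to_netcdf(path)
        ds = xr.open_dataset(path, engine="scipy")
        assert ds.attrs["run_mode"] == "active"
        np.testing.assert_allclose(ds["lat"].values, tr.lat)
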