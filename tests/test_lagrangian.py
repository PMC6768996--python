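"""Particle advection, seeding, experiments and beaching trajectories."""
import numpy as np
import pytest
from scipy import stats

from dfadrift.density import DeploymentDensity
from dfadrift.geo import GridSpec, LandMask, haversine_km
from dfadrift.lagrangian import (STATUS_EXPIRED, STATUS_HALTED,
                                 ExperimentSchedule, VelocityField, advect,
                                 coastal_cell_mask,
                                 coastal_density_correlation,
                                 extract_beaching_trajectories,
                                 mean_daily_cell_counts, run_experiment,
                                 seed_uniform, seed_weighted,
                                 solid_body_field)
from dfadrift.synth import (SyntheticWorldConfig, gen_velocity_field,
                            make_land_mask)


def uniform_field(u=-0.3, v=0.0, bounds=(140, 170, -8, 4), step=0.5):
    grid = GridSpec(*bounds, step)
    nlat, nlon = grid.n_lat, grid.n_lon
    return VelocityField(grid.lon_centers, grid.lat_centers, [0.0],
                         np.full((1, nlat, nlon), u),
                         np.full((1, nlat, nlon), v))


class TestAdvect:
    def test_zero_flow_keeps_particles_stationary(self):
        f = uniform_field(0.0, 0.0)
        tr = advect(np.array([150.0, 160.0]), np.array([0.0, -3.0]), f,
                    duration_h=240, dt_h=1.0)
        np.testing.assert_allclose(tr.end_lon, [150.0, 160.0])
        np.testing.assert_allclose(tr.end_lat, [0.0, -3.0])

    def test_uniform_westward_flow_matches_analytic_displacement(self):
        # 0.3 m/s for 10 days = 259.2 km along the equator
        f = uniform_field(-0.3, 0.0)
        tr = advect(np.array([160.0]), np.array([0.0]), f,
                    duration_h=240, dt_h=1.0)
        d = haversine_km(160.0, 0.0, tr.end_lon[0], tr.end_lat[0])
        assert d == pytest.approx(259.2, abs=0.5)
        assert tr.end_lon[0] < 160.0

    def test_solid_body_rotation_returns_to_start(self):
        omega = 2 * np.pi / (10 * 86400.0)          # 10-day period
        field = solid_body_field(150.0, 0.0, omega)
        tr = advect(np.array([151.0]), np.array([0.0]), field,
                    duration_h=240, dt_h=1.0)
        err = haversine_km(151.0, 0.0, tr.end_lon[0], tr.end_lat[0])
        assert err < 1.0

    def test_rk4_fourth_order_convergence(self):
        # halving dt must reduce the closed-orbit error by about 2^4
        omega = 2 * np.pi / (10 * 86400.0)
        field = solid_body_field(150.0, 0.0, omega)
        errs = []
        for dt in (2.0, 1.0, 0.5):
            tr = advect(np.array([151.0]), np.array([0.0]), field,
                        duration_h=240, dt_h=dt)
            errs.append(haversine_km(151.0, 0.0, tr.end_lon[0],
                                     tr.end_lat[0]))
        for a, b in zip(errs, errs[1:]):
            assert a / b == pytest.approx(16.0, rel=0.3)

    def test_land_halts_particle_at_last_sea_position(self):
        grid = GridSpec(150, 160, -6, 0, 1.0)
        cfg = SyntheticWorldConfig(grid=grid, islands=[(153.0, -3.0, 60.0)],
                                   jet_speed=0.3, eddy_count=0,
                                   time_span_days=40.0, field_cell_size=0.5,
                                   mask_cell_size=0.05, rng_seed=0)
        mask = make_land_mask(cfg)
        field = gen_velocity_field(cfg, mask)
        # released due east of the island within its latitudinal span
        n = 200
        rng = np.random.default_rng(1)
        lat0 = rng.uniform(-3.4, -2.6, n)
        lon0 = np.full(n, 156.5)
        tr = advect(lon0, lat0, field, duration_h=40 * 24, dt_h=1.0,
                    mask=mask, domain=grid)
        halted = tr.status == STATUS_HALTED
        assert halted.mean() >= 0.99
        # eastern flank: every stranding longitude is east of the centre
        assert np.all(tr.end_lon[halted] > 153.0)
        assert np.all(~mask.on_land(tr.end_lon[halted], tr.end_lat[halted]))

    def test_bit_reproducible_for_fixed_inputs(self):
        f = uniform_field(-0.2, 0.05)
        a = advect(np.array([155.0]), np.array([-2.0]), f, duration_h=120,
                   dt_h=1.0)
        b = advect(np.array([155.0]), np.array([-2.0]), f, duration_h=120,
                   dt_h=1.0)
        np.testing.assert_array_equal(a.lon, b.lon)
        np.testing.assert_array_equal(a.end_lat, b.end_lat)

    def test_depth_axis_is_averaged_over_top_50m(self):
        import xarray as xr
        lon = np.arange(150.25, 160, 0.5)
        lat = np.arange(-5.75, 0, 0.5)
        depth = np.array([5.0, 25.0, 45.0, 80.0])
        u = np.zeros((1, len(depth), len(lat), len(lon)))
        for k, val in enumerate([-0.1, -0.2, -0.3, -5.0]):
            u[0, k] = val
        ds = xr.Dataset(
            {"u": (("time", "depth", "lat", "lon"), u),
             "v": (("time", "depth", "lat", "lon"), np.zeros_like(u))},
            coords={"time": [0.0], "depth": depth, "lat": lat, "lon": lon})
        f = VelocityField.from_dataset(ds)
        # the 80 m level is excluded; mean of the top three levels
        assert np.allclose(f.u, -0.2)


class TestSeeding:
    def test_uniform_all_sea_count_and_bounds(self):
        grid = GridSpec(150, 160, -5, 5, 1.0)
        rng = np.random.default_rng(0)
        lon, lat = seed_uniform(grid, None, 5, rng)
        assert len(lon) == 5 * grid.n_cells
        assert grid.contains(lon, lat).all()

    def test_study_domain_cohort_exceeds_11000(self):
        grid = GridSpec(130, -140, -15, 10, 1.0)
        rng = np.random.default_rng(1)
        lon, lat = seed_uniform(grid, None, 5, rng)
        assert len(lon) == 11250
        assert len(lon) >= 11000

    def test_same_seed_identical_positions(self):
        grid = GridSpec(150, 160, -5, 0, 1.0)
        a = seed_uniform(grid, None, 3, np.random.default_rng(7))
        b = seed_uniform(grid, None, 3, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_seeds_avoid_land(self):
        grid = GridSpec(150, 160, -6, 0, 1.0)
        cfg = SyntheticWorldConfig(grid=grid, islands=[(155.0, -3.0, 90.0)],
                                   mask_cell_size=0.1, rng_seed=0)
        mask = make_land_mask(cfg)
        lon, lat = seed_uniform(grid, mask, 5, np.random.default_rng(2))
        assert not mask.on_land(lon, lat).any()

    def test_weighted_point_mass_concentrates(self):
        gx = np.arange(150.05, 160, 0.1)
        gy = np.arange(-4.95, 0, 0.1)
        dens = np.zeros((len(gy), len(gx)))
        iy, ix = 25, 50
        dens[iy, ix] = 1.0
        kde = DeploymentDensity(gx, gy, dens, (0.05, 0.05))
        lon, lat = seed_weighted(kde, 500, None, np.random.default_rng(3))
        d = haversine_km(lon, lat, gx[ix], gy[iy])
        assert np.quantile(d, 0.99) <= 2 * 0.1 * 111.2

    def test_weighted_uniform_surface_matches_uniform_seeding(self):
        grid = GridSpec(150, 160, -5, 0, 1.0)
        gx = np.arange(150.05, 160, 0.1)
        gy = np.arange(-4.95, 0, 0.1)
        kde = DeploymentDensity(gx, gy, np.full((len(gy), len(gx)), 0.02),
                                (0.3, 0.3))
        lon, lat = seed_weighted(kde, 10000, None, np.random.default_rng(4))
        counts = np.bincount(grid.flat_cell_of(lon, lat),
                             minlength=grid.n_cells)
        chi = stats.chisquare(counts, sum_check=False)
        assert chi.pvalue > 0.01

    def test_zero_particles_is_empty(self):
        kde = DeploymentDensity(np.array([150.5]), np.array([-2.5]),
                                np.array([[1.0]]), (0.1, 0.1))
        lon, lat = seed_weighted(kde, 0, None, np.random.default_rng(5))
        assert len(lon) == 0


class TestExperiment:
    def test_weekly_cohorts_over_28_days(self):
        grid = GridSpec(150, 155, -3, 0, 1.0)
        f = uniform_field(0.0, 0.0, bounds=(150, 155, -3, 0))
        sched = ExperimentSchedule(t_start_h=0.0, t_end_h=28 * 24.0,
                                   spinup_days=0.0, max_life_days=30.0,
                                   dt_h=6.0)
        store = run_experiment("uniform", f, None, sched, grid=grid,
                               mean_density=2, seed=0)
        assert len(store.cohorts) == 5            # days 0, 7, 14, 21, 28
        assert store.total_released() == 5 * 2 * grid.n_cells

    def test_spinup_cohorts_excluded_from_analysis(self):
        grid = GridSpec(150, 155, -3, 0, 1.0)
        f = uniform_field(0.0, 0.0, bounds=(150, 155, -3, 0))
        sched = ExperimentSchedule(t_start_h=0.0, t_end_h=28 * 24.0,
                                   spinup_days=28.0, max_life_days=30.0,
                                   dt_h=6.0)
        store = run_experiment("uniform", f, None, sched, grid=grid,
                               mean_density=2, seed=0)
        assert len(store.analysis_cohorts()) == 1  # only the final release

    def test_status_conservation(self):
        grid = GridSpec(150, 160, -6, 0, 1.0)
        cfg = SyntheticWorldConfig(grid=grid, islands=[(153.0, -3.0, 60.0)],
                                   jet_speed=0.3, eddy_count=0,
                                   time_span_days=30.0, field_cell_size=0.5,
                                   mask_cell_size=0.1, rng_seed=0)
        mask = make_land_mask(cfg)
        field = gen_velocity_field(cfg, mask)
        sched = ExperimentSchedule(t_start_h=0.0, t_end_h=30 * 24.0,
                                   spinup_days=0.0, max_life_days=20.0,
                                   dt_h=3.0)
        store = run_experiment("uniform", field, mask, sched, grid=grid,
                               mean_density=2, seed=1)
        for cohort in store.cohorts:
            counts = cohort.status_counts()
            assert sum(counts.values()) == cohort.n_particles


class TestBeachingTrajectories:
    @staticmethod
    def straight_store(release_lons, beach_lon=None, days=30):
        """Particles in a pure westward jet, recorded daily."""
        grid = GridSpec(140, 170, -6, 0, 1.0)
        f = uniform_field(-0.3, 0.0, bounds=(140, 170, -6, 0))
        sched = ExperimentSchedule(t_start_h=0.0, t_end_h=days * 24.0,
                                   spinup_days=0.0, max_life_days=days,
                                   dt_h=1.0)
        lat = np.full(len(release_lons), -3.0)
        tr = advect(np.asarray(release_lons, float), lat, f,
                    duration_h=days * 24.0, dt_h=1.0, domain=grid)
        from dfadrift.lagrangian import TrajectoryStore
        return TrajectoryStore("uniform", sched, [tr], 0), grid

    def test_crossing_two_cells_yields_two_trajectories(self):
        store, grid = self.straight_store([160.7])
        # westward drift crosses both cells within the window
        cells = {int(grid.flat_cell_of(159.5, -3.0)),
                 int(grid.flat_cell_of(158.5, -3.0))}
        trajs = extract_beaching_trajectories(store, cells, grid)
        assert len(trajs) == 2
        assert {t.cell for t in trajs} == cells

    def test_non_crossing_particle_yields_none(self):
        store, grid = self.straight_store([160.7], days=5)
        cells = {int(grid.flat_cell_of(140.5, -3.0))}
        assert extract_beaching_trajectories(store, cells, grid) == []

    def test_release_inside_cell_has_zero_drift(self):
        store, grid = self.straight_store([160.7])
        cells = {int(grid.flat_cell_of(160.7, -3.0))}
        trajs = extract_beaching_trajectories(store, cells, grid)
        assert len(trajs) == 1
        assert trajs[0].drift_days == 0.0

    def test_entry_time_matches_jet_transit(self):
        store, grid = self.straight_store([160.5])
        target = int(grid.flat_cell_of(157.5, -3.0))
        trajs = extract_beaching_trajectories(store, {target}, grid)
        # 2.5 degrees at 0.3 m/s ~ 10.7 days, resolved at daily cadence
        expect = 2.5 * 111.19 * np.cos(np.radians(-3.0)) / (0.3 * 86.4)
        assert trajs[0].drift_days == pytest.approx(expect, abs=1.0)


class TestCoastalCorrelation:
    def test_identical_fields_correlate_perfectly(self):
        grid = GridSpec(150, 160, -6, 0, 1.0)
        cfg = SyntheticWorldConfig(grid=grid, islands=[(155.0, -3.0, 60.0)],
                                   mask_cell_size=0.1, rng_seed=0)
        mask = make_land_mask(cfg)
        coastal = coastal_cell_mask(grid, mask)
        assert coastal.sum() >= 3
        rng = np.random.default_rng(0)
        a = rng.random((grid.n_lat, grid.n_lon))
        r, n = coastal_density_correlation(a, a, coastal)
        assert r == pytest.approx(1.0)
        assert n == int(coastal.sum())
        r2, _ = coastal_density_correlation(a, a.mean() - (a - a.mean()),
                                            coastal)
        assert r2 == pytest.approx(-1.0)

    def test_too_few_cells_raises(self):
        coastal = np.zeros((5, 5), bool)
        coastal[0, 0] = True
        with pytest.raises(ValueError):
            coastal_density_correlation(np.ones((5, 5)), np.ones((5, 5)),
                                        coastal)
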