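"""Synthetic world generator: velocity fields, fleets, ground truth."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dfadrift.geo import KM_PER_DEG, GridSpec, haversine_km
from dfadrift.lagrangian import advect
from dfadrift.synth import (FleetConfig, SyntheticWorldConfig,
                            gen_cell_quarter_table, gen_fleet_tracks,
                            gen_velocity_field, make_land_mask,
                            solid_body_velocity_field)
from conftest import drift_only_fleet


def plain_world(grid=None, **kw):
    grid = grid or GridSpec(150, 170, -6, 0, 1.0)
    defaults = dict(grid=grid, islands=[], eddy_count=0, jet_speed=0.3,
                    time_span_days=30.0, field_cell_size=0.5,
                    mask_cell_size=0.25, rng_seed=0)
    defaults.update(kw)
    return SyntheticWorldConfig(**defaults)


class TestVelocityField:
    def test_pure_jet_is_uniform_westward(self):
        field = gen_velocity_field(plain_world())
        assert np.allclose(field.u, -0.3)
        assert np.allclose(field.v, 0.0)

    def test_same_seed_is_bit_identical(self):
        cfg = plain_world(eddy_count=5, eddy_amplitude=0.1)
        f1 = gen_velocity_field(cfg)
        f2 = gen_velocity_field(cfg)
        np.testing.assert_array_equal(f1.u, f2.u)
        np.testing.assert_array_equal(f1.v, f2.v)

    def test_land_cells_have_zero_velocity(self):
        cfg = plain_world(islands=[(160.0, -3.0, 80.0)], mask_cell_size=0.1)
        mask = make_land_mask(cfg)
        field = gen_velocity_field(cfg, mask)
        lon_g, lat_g = np.meshgrid(field.lon, field.lat)
        on_land = mask.on_land(lon_g.ravel(), lat_g.ravel()).reshape(lon_g.shape)
        assert on_land.any()
        assert np.all(field.u[:, on_land] == 0.0)

    def test_solid_body_preset_has_constant_curl(self):
        # finite-difference curl of the rotation preset ~ 2*omega everywhere
        omega = 2 * np.pi / (10 * 86400.0)
        grid = GridSpec(148, 152, -2, 2, 1.0)
        f = solid_body_velocity_field(grid, 150.0, 0.0, omega, cell_size=0.1)
        dx = (f.lon[1] - f.lon[0]) * KM_PER_DEG * 1000.0
        dy = (f.lat[1] - f.lat[0]) * KM_PER_DEG * 1000.0
        dvdx = np.gradient(f.v[0], axis=1) / dx
        dudy = np.gradient(f.u[0], axis=0) / dy
        curl = dvdx - dudy
        inner = curl[5:-5, 5:-5]
        assert np.allclose(inner, 2 * omega, rtol=0.02)

    def test_netcdf_round_trip(self, tmp_path):
        from dfadrift.lagrangian import VelocityField
        field = gen_velocity_field(plain_world())
        path = tmp_path / "field.nc"
        field.to_netcdf(path)
        back = VelocityField.from_netcdf(path)
        np.testing.assert_allclose(back.u, field.u)
        np.testing.assert_allclose(back.time_h, field.time_h)


class TestFleet:
    def test_no_recovery_no_islands_single_segment(self):
        cfg = plain_world()
        field = gen_velocity_field(cfg)
        fleet = FleetConfig(n_buoys=20, predeploy_probability=0.0,
                            recovery_probability=0.0,
                            deactivation_probability=0.0,
                            drift_noise_km=0.0, rng_seed=4)
        tracks, truth, events = gen_fleet_tracks(fleet, field, None, cfg.grid)
        counts = events.groupby("event").size()
        assert counts.get("deployment", 0) == 20
        assert counts.get("beaching", 0) == 0
        assert (truth["label"] == "at_sea").all()

    def test_ground_truth_row_conservation(self, beach_world,
                                           beach_fleet_noise_free):
        tracks, truth, _ = beach_fleet_noise_free
        assert len(tracks) == len(truth)
        pd.testing.assert_frame_equal(
            tracks[["buoy_id", "timestamp"]],
            truth[["buoy_id", "timestamp"]])

    def test_buoy_east_of_island_beaches_on_eastern_flank(self):
        # pure westward jet at 0.3 m/s; deployment 150 km due east of an
        # island of radius 60 km -> stranding after ~(150-60)/25.9 ~ 3.5 d
        grid = GridSpec(150, 160, -6, 0, 1.0)
        island = (153.0, -3.0, 60.0)
        cfg = SyntheticWorldConfig(grid=grid, islands=[island], jet_speed=0.3,
                                   eddy_count=0, time_span_days=15.0,
                                   field_cell_size=0.5, mask_cell_size=0.05,
                                   rng_seed=0)
        mask = make_land_mask(cfg)
        field = gen_velocity_field(cfg, mask)
        dep_lon = island[0] + 150.0 / (KM_PER_DEG * np.cos(np.radians(-3.0)))
        fleet = FleetConfig(n_buoys=1, predeploy_probability=0.0,
                            recovery_probability=0.0,
                            deactivation_probability=0.0, drift_noise_km=0.0,
                            fixed_deployments=[(dep_lon, -3.0)], rng_seed=0)
        _, _, events = gen_fleet_tracks(fleet, field, mask, grid)
        b = events[events.event == "beaching"]
        assert len(b) == 1
        assert b.lon.iloc[0] > island[0]            # eastern flank
        d_island = haversine_km(b.lon.iloc[0], b.lat.iloc[0], *island[:2])
        assert d_island == pytest.approx(60.0, abs=10.0)
        drift_days = (b.time.iloc[0] - events.time.min()).total_seconds() / 86400.0
        expect = (150.0 - 60.0) / (0.3 * 86.4)      # distance / jet speed
        assert drift_days == pytest.approx(expect, rel=0.25)

    def test_zero_noise_drift_matches_integrator(self):
        # over 30 days the recorded drift must track direct RK4 integration
        cfg = plain_world(eddy_count=3, eddy_amplitude=0.1, rng_seed=6)
        field = gen_velocity_field(cfg)
        # deploy in the east so no buoy reaches the domain edge in 30 days
        fleet = FleetConfig(n_buoys=5, predeploy_probability=0.0,
                            recovery_probability=0.0,
                            deactivation_probability=0.0,
                            fixed_deployments=[(168.0, -2.0), (167.0, -4.0),
                                               (166.5, -1.0), (165.5, -5.0),
                                               (164.0, -3.0)],
                            drift_noise_km=0.0, rng_seed=7)
        tracks, _, events = gen_fleet_tracks(fleet, field, None, cfg.grid)
        for b, g in tracks.groupby("buoy_id"):
            g = g.sort_values("timestamp")
            t0 = (g.timestamp.iloc[0] - pd.Timestamp("2016-01-01")) \
                .total_seconds() / 3600.0
            dur = (g.timestamp.iloc[-1] - g.timestamp.iloc[0]) \
                .total_seconds() / 3600.0
            tr = advect(np.array([g.lon.iloc[0]]), np.array([g.lat.iloc[0]]),
                        field, t0_h=t0, duration_h=dur, dt_h=1.0,
                        record_every_h=24.0)
            err = haversine_km(g.lon.iloc[-1], g.lat.iloc[-1],
                               tr.end_lon[0], tr.end_lat[0])
            assert err < 1.0

    def test_hotspot_deployments_match_target_surface(self):
        # chi-square goodness of fit of deployment draws against the
        # two-component Gaussian target, binned on the 1-deg grid
        grid = GridSpec(150, 170, -10, 0, 1.0)
        cfg = plain_world(grid=grid)
        field = gen_velocity_field(cfg)
        hot = [(160.0, -5.0, 0.8), (155.0, -2.5, 0.6)]
        fleet = FleetConfig(n_buoys=5000, predeploy_probability=0.0,
                            recovery_probability=0.0,
                            deactivation_probability=1.0,   # ping once, stop fast
                            deployment_distribution="hotspot", hotspots=hot,
                            drift_noise_km=0.0, span_days=2.0, rng_seed=8)
        _, _, events = gen_fleet_tracks(fleet, field, None, grid)
        dep = events[events.event == "deployment"].drop_duplicates("buoy_id")
        flat = grid.flat_cell_of(dep.lon.to_numpy(), dep.lat.to_numpy())
        obs = np.bincount(flat, minlength=grid.n_cells)
        # exact cell masses of the domain-truncated Gaussian mixture
        p = np.zeros((grid.n_lat, grid.n_lon))
        for hl, hb, sd in hot:
            px = np.diff(stats.norm.cdf(grid.lon_edges, hl, sd))
            py = np.diff(stats.norm.cdf(grid.lat_edges, hb, sd))
            p += np.outer(py, px)
        p = (p / p.sum()).ravel()
        keep = p * len(dep) >= 5
        chi = stats.chisquare(obs[keep], len(dep) * p[keep] / p[keep].sum(),
                              sum_check=False)
        assert chi.pvalue > 0.01

    def test_beached_buoys_ping_stationary_then_stop(self, beach_world,
                                                     beach_fleet_noise_free):
        tracks, truth, events = beach_fleet_noise_free
        b = events[events.event == "beaching"]
        assert len(b) >= 20
        one = b.iloc[0]
        g = tracks[tracks.buoy_id == one.buoy_id].sort_values("timestamp")
        tail = g.tail(6)
        assert tail.lon.nunique() == 1 and tail.lat.nunique() == 1


class TestCellQuarterTable:
    def test_planted_sets_are_disjoint_and_sized(self):
        rec, prone, resil = gen_cell_quarter_table(200, rng_seed=0)
        assert len(prone) == len(resil) == 20
        assert not prone & resil
        assert len(rec) == 200

    def test_counts_follow_the_regression_surface(self):
        rec, _, _ = gen_cell_quarter_table(400, sigma=0.01,
                                           outlier_fraction=0.0, rng_seed=1)
        fit = np.polyfit(rec.density[rec.quarter == 1],
                         rec.n_beaching[rec.quarter == 1], 1)
        assert fit[0] == pytest.approx(0.5, abs=0.01)
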