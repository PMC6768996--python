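"""Shared synthetic worlds and helpers for the test suite.

Heavy fixtures are session-scoped so that the beaching-rule, cleaning and
connectivity tests reuse the same simulated fleets.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dfadrift.cleaning import split_segments
from dfadrift.geo import GridSpec
from dfadrift.synth import (FleetConfig, SyntheticWorldConfig,
                            gen_fleet_tracks, gen_velocity_field,
                            make_land_mask)


def segments_from_truth(truth: pd.DataFrame):
    """Drift segments cut at the ground-truth at-sea/on-board labels."""
    segs = []
    for _, g in truth.groupby("buoy_id", sort=False):
        segs.extend(split_segments(g, g["label"].to_numpy()))
    return segs


@pytest.fixture(scope="session")
def beach_world():
    """Westward-jet world with three islands; drift-only fleets beach on
    their eastern flanks.  Used by the beaching-rule tests."""
    grid = GridSpec(150, 175, -8, 0, 1.0)
    cfg = SyntheticWorldConfig(
        grid=grid,
        islands=[(153.0, -4.0, 70.0), (156.0, -6.5, 50.0), (152.5, -1.5, 50.0)],
        jet_speed=0.4, eddy_count=0, time_span_days=60.0,
        field_interval_h=24.0, field_cell_size=0.5, mask_cell_size=0.05,
        rng_seed=1)
    mask = make_land_mask(cfg)
    field = gen_velocity_field(cfg, mask)
    return {"cfg": cfg, "grid": grid, "mask": mask, "field": field}


def drift_only_fleet(world, noise_km: float, seed: int, n_buoys: int = 200):
    fleet = FleetConfig(n_buoys=n_buoys, predeploy_probability=0.0,
                        recovery_probability=0.0,
                        deactivation_probability=0.005,
                        drift_noise_km=noise_km, rng_seed=seed)
    return gen_fleet_tracks(fleet, world["field"], world["mask"],
                            world["grid"])


@pytest.fixture(scope="session")
def beach_fleet_noise_free(beach_world):
    return drift_only_fleet(beach_world, 0.0, seed=2)


@pytest.fixture(scope="session")
def beach_fleet_noisy(beach_world):
    return drift_only_fleet(beach_world, 0.5, seed=2)


@pytest.fixture(scope="session")
def vessel_world():
    """World with a port, eddies, and fleets that include vessel phases;
    used by the cleaning/classification tests."""
    grid = GridSpec(150, 175, -8, 0, 1.0)
    cfg = SyntheticWorldConfig(
        grid=grid,
        islands=[(153.0, -4.0, 70.0), (156.0, -6.5, 50.0)],
        jet_speed=0.3, eddy_count=4, eddy_amplitude=0.1,
        time_span_days=45.0, field_interval_h=24.0, field_cell_size=0.5,
        mask_cell_size=0.05, ports=[(156.0, -6.97)], rng_seed=1)
    mask = make_land_mask(cfg)
    field = gen_velocity_field(cfg, mask)
    kwargs = dict(n_buoys=120, predeploy_probability=0.7,
                  recovery_probability=0.03, deactivation_probability=0.01,
                  drift_noise_km=0.5)
    train = gen_fleet_tracks(FleetConfig(rng_seed=11, **kwargs), field, mask,
                             grid)
    test = gen_fleet_tracks(FleetConfig(rng_seed=22, **kwargs), field, mask,
                            grid)
    return {"cfg": cfg, "grid": grid, "mask": mask, "field": field,
            "train": train, "test": test}
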