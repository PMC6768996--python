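"""Canonical verification experiments at the study's design conditions.

Each function builds its inputs from the synthetic-world generator (or a
closed-form flow), runs the corresponding pipeline stage(s), and returns
the measured quantities.  They are used by the test suite and by the
repository's acceptance script; the problem sizes are chosen so the whole
battery runs in a few minutes on one core.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import cleaning as cl
from . import lagrangian as lag
from .beaching import RegionSpec, detect_all
from .cells import (CLASS_PRONE, CLASS_RESILIENT, classify_cells,
                    fit_beaching_model)
from .cleaning import split_segments
from .density import deployment_kde, standardized_density
from .geo import GridSpec, haversine_km
from .synth import (FleetConfig, SyntheticWorldConfig, gen_cell_quarter_table,
                    gen_fleet_tracks, gen_velocity_field, make_land_mask)

__all__ = [
    "seeding_rate",
    "advection_oracles",
    "beaching_fidelity",
    "cleaning_accuracy",
    "classification_recovery",
    "connectivity_experiment",
    "scenario_contrast",
]


def _segments_from_truth(truth: pd.DataFrame):
    segs = []
    for _, g in truth.groupby("buoy_id", sort=False):
        segs.extend(split_segments(g, g["label"].to_numpy()))
    return segs


def seeding_rate(seed: int = 0) -> dict:
    """Per-cohort particle count for the 130E-140W, 15S-10N study domain at
    a mean density of 5 per one-degree cell (90 x 25 cells)."""
    grid = GridSpec(130, -140, -15, 10, 1.0)
    rng = np.random.default_rng(seed)
    lon, lat = lag.seed_uniform(grid, None, 5, rng)
    return {"per_cohort_seed_count": len(lon), "n_cells": grid.n_cells}


def advection_oracles(seed: int = 0) -> dict:
    """RK4 accuracy against closed-form flows.

    Uniform flow: position error after 10 days at 0.3 m/s.  Solid-body
    rotation: return-to-start error after one 10-day period at dt = 1 h, and
    the error-reduction factor when halving dt (expected ~16 for RK4).
    """
    grid = GridSpec(140, 170, -8, 4, 0.5)
    f = lag.VelocityField(grid.lon_centers, grid.lat_centers, [0.0],
                          np.full((1, grid.n_lat, grid.n_lon), -0.3),
                          np.zeros((1, grid.n_lat, grid.n_lon)))
    tr = lag.advect(np.array([160.0]), np.array([0.0]), f,
                    duration_h=240.0, dt_h=1.0)
    d = haversine_km(160.0, 0.0, tr.end_lon[0], tr.end_lat[0])
    uniform_err = abs(d - 0.3 * 86.4 * 10.0)

    omega = 2 * np.pi / (10 * 86400.0)
    field = lag.solid_body_field(150.0, 0.0, omega)
    errs = {}
    for dt in (1.0, 0.5):
        tr = lag.advect(np.array([151.0]), np.array([0.0]), field,
                        duration_h=240.0, dt_h=dt)
        errs[dt] = haversine_km(151.0, 0.0, tr.end_lon[0], tr.end_lat[0])
    return {"uniform_flow_error_km": float(uniform_err),
            "rotation_return_error_km": float(errs[1.0]),
            "halving_dt_error_ratio": float(errs[1.0] / errs[0.5])}


def _beach_world():
    grid = GridSpec(150, 175, -8, 0, 1.0)
    cfg = SyntheticWorldConfig(
        grid=grid,
        islands=[(153.0, -4.0, 70.0), (156.0, -6.5, 50.0), (152.5, -1.5, 50.0)],
        jet_speed=0.4, eddy_count=0, time_span_days=60.0,
        field_interval_h=24.0, field_cell_size=0.5, mask_cell_size=0.05,
        rng_seed=1)
    mask = make_land_mask(cfg)
    field = gen_velocity_field(cfg, mask)
    return grid, mask, field


def beaching_fidelity(seed: int = 0, n_buoys: int = 200) -> dict:
    """Detected beaching events against ground truth for a drift-only fleet.

    Noise-free transmissions: the detected (buoy, cell) multiset must equal
    the ground truth.  With 0.5 km drift noise and a 1 km same-location
    tolerance, precision and recall are reported.
    """
    grid, mask, field = _beach_world()
    out = {}
    for tag, noise in (("noise_free", 0.0), ("noisy", 0.5)):
        fleet = FleetConfig(n_buoys=n_buoys, predeploy_probability=0.0,
                            recovery_probability=0.0,
                            deactivation_probability=0.005,
                            drift_noise_km=noise, rng_seed=seed)
        _, truth, events = gen_fleet_tracks(fleet, field, mask, grid)
        segs = _segments_from_truth(truth)
        detected, _ = detect_all(segs, mask, grid, same_loc_tol_km=1.0)
        tb = events[events.event == "beaching"]
        truth_set = set(zip(tb.buoy_id,
                            grid.flat_cell_of(tb.lon.to_numpy(),
                                              tb.lat.to_numpy(),
                                              strict=False)))
        det_set = set((e.buoy_id, e.cell) for e in detected)
        tp = len(det_set & truth_set)
        out[f"{tag}_n_truth"] = len(truth_set)
        out[f"{tag}_n_detected"] = len(det_set)
        out[f"{tag}_precision"] = tp / len(det_set) if det_set else 0.0
        out[f"{tag}_recall"] = tp / len(truth_set) if truth_set else 0.0
    out["noise_free_exact_match"] = float(
        out["noise_free_precision"] == 1.0
        and out["noise_free_recall"] == 1.0)
    return out


def cleaning_accuracy(seed: int = 0, n_buoys: int = 120) -> dict:
    """Per-position at-sea/on-board accuracy of a classifier trained on one
    synthetic fleet and evaluated on an independent fleet from the same
    world, plus the position-conservation balance of the pipeline."""
    grid = GridSpec(150, 175, -8, 0, 1.0)
    cfg = SyntheticWorldConfig(
        grid=grid, islands=[(153.0, -4.0, 70.0), (156.0, -6.5, 50.0)],
        jet_speed=0.3, eddy_count=4, eddy_amplitude=0.1, time_span_days=45.0,
        field_cell_size=0.5, mask_cell_size=0.05, ports=[(156.0, -6.97)],
        rng_seed=1)
    mask = make_land_mask(cfg)
    field = gen_velocity_field(cfg, mask)
    kwargs = dict(n_buoys=n_buoys, predeploy_probability=0.7,
                  recovery_probability=0.03, deactivation_probability=0.01,
                  drift_noise_km=0.5)
    _, tr_truth, _ = gen_fleet_tracks(FleetConfig(rng_seed=seed + 1, **kwargs),
                                      field, mask, grid)
    te_tracks, te_truth, _ = gen_fleet_tracks(
        FleetConfig(rng_seed=seed + 2, **kwargs), field, mask, grid)
    feats, labels = [], []
    for _, g in tr_truth.groupby("buoy_id", sort=False):
        if len(g) < 3:
            continue
        feats.append(cl.compute_features(g, mask=mask))
        labels.append(g["label"].to_numpy())
    model = cl.train_position_classifier(pd.concat(feats),
                                         np.concatenate(labels),
                                         rng_seed=seed)
    res = cl.clean_and_segment(te_tracks, model, mask=mask)
    merged = res.labels.merge(te_truth[["buoy_id", "timestamp", "label"]],
                              on=["buoy_id", "timestamp"],
                              suffixes=("_pred", "_true"))
    acc = float((merged.label_pred == merged.label_true).mean())
    return {"position_accuracy": acc,
            "holdout_accuracy": model.holdout_accuracy,
            "conservation_balance": res.accounting()["balance"],
            "n_positions": len(merged)}


def classification_recovery(seed: int = 0) -> dict:
    """Recovery of planted 5-sigma outlier cells (exact set equality at
    n = 200) and of injected quarter offsets (n = 400, sigma = 0.5)."""
    rec, prone, resil = gen_cell_quarter_table(200, sigma=0.5, rng_seed=seed)
    model = fit_beaching_model(rec)
    out = classify_cells(rec, model.residuals)
    got_p = set(out.index[out.cell_class == CLASS_PRONE])
    got_r = set(out.index[out.cell_class == CLASS_RESILIENT])

    rec4, _, _ = gen_cell_quarter_table(400, sigma=0.5, outlier_fraction=0.0,
                                        rng_seed=seed + 1)
    offsets = fit_beaching_model(rec4).quarter_offsets()
    errors = [abs(offsets[q] - t) for q, t in ((2, 3.0), (3, 0.0), (4, -3.0))]
    return {"prone_exact": float(got_p == prone),
            "resilient_exact": float(got_r == resil),
            "n_records": len(rec),
            "quarter_offset_max_error": float(max(errors))}


def connectivity_experiment(seed: int = 0, mean_density: int = 4) -> dict:
    """Westward-jet source-sink experiment.

    Uniformly seeded particles drift west at 0.3 m/s onto a single island;
    connectivity rows must sum to 100 %, the modal source band must shift
    monotonically eastward with drift-time bin, and the median of
    drift_time / (distance / jet speed) must be 1 within 20 %.
    """
    from .connectivity import LagBinSpec, connectivity_matrix

    grid = GridSpec(130, 175, -6, 0, 1.0)
    cfg = SyntheticWorldConfig(
        grid=grid, islands=[(131.5, -3.0, 80.0)], jet_speed=0.3,
        eddy_count=0, time_span_days=200.0, field_interval_h=48.0,
        field_cell_size=0.5, mask_cell_size=0.1, rng_seed=3)
    mask = make_land_mask(cfg)
    field = gen_velocity_field(cfg, mask)
    sched = lag.ExperimentSchedule(t_start_h=0.0, t_end_h=200 * 24.0,
                                   spinup_days=0.0, max_life_days=200.0,
                                   dt_h=2.0)
    store = lag.run_experiment("uniform", field, mask, sched, grid=grid,
                               mean_density=mean_density, seed=seed)
    land1 = mask.land_fraction(grid) > 0
    beach_cells = set(np.nonzero(land1.ravel())[0].tolist())
    trajs = lag.extract_beaching_trajectories(store, beach_cells, grid)

    bands = (140.0, 150.0, 160.0)
    spec = RegionSpec(north_lat=5.0, lon_edges=bands,
                      south_labels=("band_0", "band_1", "band_2", "band_3"))
    mat = connectivity_matrix(trajs, LagBinSpec(), None, spec, grid=grid)
    sums = mat.groupby(["beaching_region", "lag_bin"],
                       observed=True)["percent"].sum()
    row_dev = float(np.abs(sums.to_numpy() - 100.0).max())

    modal = []
    for _, g in mat.groupby("lag_bin", observed=True):
        top = g.sort_values(["count", "source_region"],
                            ascending=[False, True]).iloc[0]
        modal.append(int(top.source_region.split("_")[1]))
    monotone = float(all(b >= a for a, b in zip(modal, modal[1:]))
                     and modal[-1] > modal[0])

    v_km_per_day = 0.3 * 86.4
    ratios = [t.drift_days / (haversine_km(t.source_lon, t.source_lat,
                                           t.entry_lon, t.entry_lat)
                              / v_km_per_day)
              for t in trajs
              if haversine_km(t.source_lon, t.source_lat,
                              t.entry_lon, t.entry_lat) > 200.0]
    return {"row_sum_max_abs_dev": row_dev,
            "modal_source_monotone_east": monotone,
            "modal_band_by_lag": modal,
            "median_drift_time_ratio": float(np.median(ratios)),
            "n_trajectories": len(trajs),
            "released": store.total_released()}


def scenario_contrast(seed: int = 0, n_buoys: int = 250) -> dict:
    """Coastal-density correlation of the two seeding scenarios against
    synthetic observed tracks deployed from a hotspot-weighted surface.

    The weighted (observed-deployment) scenario must correlate better than
    the uniform scenario, the qualitative analogue of the study design.
    """
    grid = GridSpec(150, 180, -10, 0, 1.0)
    cfg = SyntheticWorldConfig(
        grid=grid,
        islands=[(153.0, -2.0, 60.0), (155.0, -8.0, 50.0),
                 (163.0, -5.0, 45.0), (170.0, -8.5, 40.0),
                 (172.0, -1.5, 45.0)],
        jet_speed=0.25, eddy_count=5, eddy_amplitude=0.08,
        time_span_days=150.0, field_interval_h=48.0, field_cell_size=0.5,
        mask_cell_size=0.1, rng_seed=5)
    mask = make_land_mask(cfg)
    field = gen_velocity_field(cfg, mask)
    fleet = FleetConfig(n_buoys=n_buoys, predeploy_probability=0.0,
                        recovery_probability=0.01,
                        deactivation_probability=0.008, drift_noise_km=0.5,
                        deployment_distribution="hotspot",
                        hotspots=[(176.0, -2.5, 1.2), (173.0, -4.5, 1.0)],
                        rng_seed=seed + 1)
    _, truth, _ = gen_fleet_tracks(fleet, field, mask, grid)
    segs = _segments_from_truth(truth)
    observed = standardized_density(
        pd.concat([s.to_dataframe() for s in segs]), grid)
    deployments = np.array([s.deployment[:2] for s in segs])
    kde = deployment_kde(deployments[:, 0], deployments[:, 1], grid,
                         lattice_step=0.25)

    sched = lag.ExperimentSchedule(t_start_h=0.0, t_end_h=150 * 24.0,
                                   spinup_days=20.0, max_life_days=130.0,
                                   dt_h=3.0)
    coastal = lag.coastal_cell_mask(grid, mask)
    result = {"n_coastal_cells": int(coastal.sum()),
              "n_segments": len(segs)}
    for scen, k in (("uniform", None), ("weighted", kde)):
        store = lag.run_experiment(scen, field, mask, sched, grid=grid,
                                   mean_density=4, kde=k, seed=seed + 2)
        sim = lag.mean_daily_cell_counts(store, grid)
        r, _ = lag.coastal_density_correlation(
            sim, observed.values.astype(float), coastal)
        result[f"pearson_{scen}"] = r
    result["weighted_minus_uniform"] = (result["pearson_weighted"]
                                        - result["pearson_uniform"])
    return result
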