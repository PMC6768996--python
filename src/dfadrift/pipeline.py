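"""End-to-end orchestration of the beaching analysis behind a single config.

Stages: synth (world + fleet) -> clean -> detect -> density/hotspots ->
classify -> simulate (uniform and weighted scenarios) -> connectivity.
Each stage reads the previous stage's files from the run directory and is
skipped when its outputs already exist, so a run is resumable from any
intermediate.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import beaching as bch
from . import cells as cc
from . import cleaning as cl
from . import connectivity as conn
from . import density as dens
from . import lagrangian as lag
from . import synth
from .geo import GridSpec, LandMask, read_ports, write_ports

log = logging.getLogger("dfadrift")

STAGES = ["synth", "clean", "detect", "density", "classify", "simulate",
          "connect"]


def demo_config(seed: int = 0) -> dict:
    """A small self-contained synthetic-world configuration."""
    return {
        "seed": seed,
        "grid": {"lon_min": 150.0, "lon_max": 170.0,
                 "lat_min": -8.0, "lat_max": 0.0, "cell_size": 1.0},
        "world": {
            "islands": [[153.0, -4.0, 60.0], [158.0, -6.5, 45.0],
                        [166.0, -2.0, 40.0]],
            "jet_speed": 0.3, "eddy_count": 4, "eddy_amplitude": 0.1,
            "eddy_radius_km": 150.0, "time_span_days": 60.0,
            "field_interval_h": 24.0, "field_cell_size": 0.5,
            "mask_cell_size": 0.1,
            "ports": [[153.0, -4.6]],
        },
        "fleet": {"n_buoys": 60, "transmission_interval_h": 1.0,
                  "deployment_distribution": "hotspot",
                  "hotspots": [[166.0, -5.0, 1.0], [161.0, -2.5, 1.2]],
                  "recovery_probability": 0.01,
                  "deactivation_probability": 0.005},
        "cleaning": {"min_duration_h": 24.0, "max_speed_kmh": 30.0,
                     "min_run": 3},
        "beaching": {"beach_dist_km": 10.0, "port_excl_km": 10.0,
                     "n_last": 3, "same_loc_tol_km": 1.0},
        "density": {"lattice_step": 0.2, "hotspot_percentile": 95.0},
        "simulate": {"mean_density": 3, "spinup_days": 10.0,
                     "max_life_days": 60.0, "dt_h": 3.0,
                     "cohort_interval_h": 168.0},
    }


def _hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


@dataclass
class RunPaths:
    out: Path

    def __post_init__(self):
        self.out = Path(self.out)
        self.out.mkdir(parents=True, exist_ok=True)

    def p(self, name: str) -> Path:
        return self.out / name


def _grid(cfg: dict) -> GridSpec:
    return GridSpec(**cfg["grid"])


def _world(cfg: dict) -> synth.SyntheticWorldConfig:
    w = dict(cfg.get("world", {}))
    w["islands"] = [tuple(i) for i in w.get("islands", [])]
    w["ports"] = [tuple(p) for p in w.get("ports", [])]
    return synth.SyntheticWorldConfig(grid=_grid(cfg),
                                      rng_seed=int(cfg.get("seed", 0)), **w)


def stage_synth(cfg: dict, paths: RunPaths, force: bool = False) -> None:
    outputs = [paths.p(n) for n in ("mask.nc", "field.nc", "ports.txt",
                                    "tracks.csv", "truth_labels.csv",
                                    "truth_events.csv")]
    if not force and all(o.exists() for o in outputs):
        log.info("synth: outputs exist, skipping")
        return
    wcfg = _world(cfg)
    mask = synth.make_land_mask(wcfg)
    field = synth.gen_velocity_field(wcfg, mask)
    fleet_kwargs = dict(cfg.get("fleet", {}))
    fleet_kwargs["hotspots"] = [tuple(h) for h in fleet_kwargs.get("hotspots", [])]
    fleet = synth.FleetConfig(rng_seed=int(cfg.get("seed", 0)) + 1,
                              **fleet_kwargs)
    tracks, truth_labels, truth_events = synth.gen_fleet_tracks(
        fleet, field, mask, wcfg.grid)
    mask.to_netcdf(paths.p("mask.nc"))
    field.to_netcdf(paths.p("field.nc"))
    write_ports(paths.p("ports.txt"), mask.ports)
    tracks.to_csv(paths.p("tracks.csv"), index=False)
    truth_labels.to_csv(paths.p("truth_labels.csv"), index=False)
    truth_events.to_csv(paths.p("truth_events.csv"), index=False)
    log.info("synth: %d transmissions from %d buoys", len(tracks),
             fleet.n_buoys)


def _load_mask(cfg, paths) -> LandMask:
    ports = read_ports(paths.p("ports.txt")) if paths.p("ports.txt").exists() \
        else None
    return LandMask.from_netcdf(paths.p("mask.nc"), ports)


def stage_clean(cfg: dict, paths: RunPaths, force: bool = False) -> None:
    outputs = [paths.p(n) for n in ("segments.csv", "labels.csv",
                                    "rejections.csv", "classifier.joblib")]
    if not force and all(o.exists() for o in outputs):
        log.info("clean: outputs exist, skipping")
        return
    seed = int(cfg.get("seed", 0))
    mask = _load_mask(cfg, paths)
    tracks = pd.read_csv(paths.p("tracks.csv"), parse_dates=["timestamp"])
    # train on an independent synthetic fleet from the same world
    wcfg = _world(cfg)
    field = lag.VelocityField.from_netcdf(paths.p("field.nc"))
    fleet_kwargs = dict(cfg.get("fleet", {}))
    fleet_kwargs["hotspots"] = [tuple(h) for h in fleet_kwargs.get("hotspots", [])]
    train_fleet = synth.FleetConfig(rng_seed=seed + 1000, **fleet_kwargs)
    tr_tracks, tr_truth, _ = synth.gen_fleet_tracks(train_fleet, field, mask,
                                                    wcfg.grid)
    feats, labels = [], []
    for _, g in tr_truth.groupby("buoy_id", sort=False):
        if len(g) < 3:
            continue
        feats.append(cl.compute_features(g, mask=mask))
        labels.append(g["label"].to_numpy())
    model = cl.train_position_classifier(pd.concat(feats),
                                         np.concatenate(labels),
                                         rng_seed=seed)
    model.save(paths.p("classifier.joblib"))
    ckw = cfg.get("cleaning", {})
    res = cl.clean_and_segment(tracks, model, mask=mask, **ckw)
    pd.concat([s.to_dataframe() for s in res.segments],
              ignore_index=True).to_csv(paths.p("segments.csv"), index=False)
    res.labels.to_csv(paths.p("labels.csv"), index=False)
    res.rejections.to_csv(paths.p("rejections.csv"), index=False)
    log.info("clean: %d segments, holdout accuracy %.3f",
             len(res.segments), model.holdout_accuracy)


def _load_segments(paths) -> list:
    df = pd.read_csv(paths.p("segments.csv"), parse_dates=["timestamp"])
    segs = []
    for (b, k), g in df.groupby(["buoy_id", "segment_index"], sort=True):
        segs.append(cl.DriftSegment(b, int(k), g["timestamp"].to_numpy(),
                                    g["lon"].to_numpy(float),
                                    g["lat"].to_numpy(float)))
    return segs


def stage_detect(cfg: dict, paths: RunPaths, force: bool = False) -> None:
    outputs = [paths.p(n) for n in ("events.csv", "events.geojson",
                                    "cell_counts.nc")]
    if not force and all(o.exists() for o in outputs):
        log.info("detect: outputs exist, skipping")
        return
    grid = _grid(cfg)
    mask = _load_mask(cfg, paths)
    segs = _load_segments(paths)
    events, _ = bch.detect_all(segs, mask, grid, **cfg.get("beaching", {}))
    cells = bch.aggregate_beaching_cells(events, grid)
    bch.events_to_dataframe(events).to_csv(paths.p("events.csv"), index=False)
    paths.p("events.geojson").write_text(
        json.dumps(bch.events_to_geojson(events)))
    bch.counts_to_dataset(cells).to_netcdf(paths.p("cell_counts.nc"),
                                           engine="scipy")
    log.info("detect: %d events in %d cells", len(events), len(cells.cells))


def stage_density(cfg: dict, paths: RunPaths, force: bool = False) -> None:
    outputs = [paths.p(n) for n in ("dfad_weeks.nc", "deploy_kde.nc",
                                    "hotspots.csv")]
    if not force and all(o.exists() for o in outputs):
        log.info("density: outputs exist, skipping")
        return
    grid = _grid(cfg)
    seg_df = pd.read_csv(paths.p("segments.csv"), parse_dates=["timestamp"])
    field = dens.standardized_density(seg_df, grid)
    field.to_dataset().to_netcdf(paths.p("dfad_weeks.nc"), engine="scipy")
    deps = seg_df.sort_values("timestamp").groupby(
        ["buoy_id", "segment_index"]).first().reset_index()
    dkw = cfg.get("density", {})
    kde = dens.deployment_kde(deps["lon"], deps["lat"], grid,
                              lattice_step=dkw.get("lattice_step", 0.1))
    kde.to_dataset().to_netcdf(paths.p("deploy_kde.nc"), engine="scipy")
    hs = dens.hotspot_cells(kde, grid,
                            percentile=dkw.get("hotspot_percentile", 95.0))
    rows, cols = np.nonzero(hs.member)
    pd.DataFrame({"cell": rows * grid.n_lon + cols, "row": rows, "col": cols,
                  "component": hs.component[rows, cols],
                  "value": hs.cell_values[rows, cols]}).to_csv(
        paths.p("hotspots.csv"), index=False)
    log.info("density: %d dfad-weeks, %d hotspot cells", field.total,
             int(hs.member.sum()))


def stage_classify(cfg: dict, paths: RunPaths, force: bool = False) -> None:
    outputs = [paths.p(n) for n in ("cell_records.csv", "classification.csv",
                                    "model_summary.txt")]
    if not force and all(o.exists() for o in outputs):
        log.info("classify: outputs exist, skipping")
        return
    grid = _grid(cfg)
    ev = pd.read_csv(paths.p("events.csv"), parse_dates=["time"])
    seg_df = pd.read_csv(paths.p("segments.csv"), parse_dates=["timestamp"])
    if ev.empty:
        for o in outputs:
            o.write_text("")
        log.warning("classify: no beaching events; wrote empty outputs")
        return
    seg_df["quarter"] = seg_df["timestamp"].dt.quarter
    records = []
    for cell in sorted(ev["cell"].unique()):
        for q in range(1, 5):
            nb = int(((ev["cell"] == cell) & (ev["quarter"] == q)).sum())
            in_q = seg_df[seg_df["quarter"] == q]
            d = dens.standardized_density(in_q, grid) if len(in_q) else None
            density = int(d.values.ravel()[cell]) if d is not None else 0
            records.append({"cell": int(cell), "quarter": q,
                            "n_beaching": nb, "density": density})
    rec = pd.DataFrame(records)
    rec.to_csv(paths.p("cell_records.csv"), index=False)
    if len(rec) >= 8 and rec["quarter"].nunique() >= 1:
        model = cc.fit_beaching_model(rec)
        out = cc.classify_cells(rec, model.residuals)
        out.to_csv(paths.p("classification.csv"), index=False)
        paths.p("model_summary.txt").write_text(model.summary_text())
        log.info("classify: R^2=%.3f over %d records", model.r_squared,
                 model.n)
    else:
        paths.p("classification.csv").write_text("")
        paths.p("model_summary.txt").write_text("too few records\n")


def stage_simulate(cfg: dict, paths: RunPaths, force: bool = False) -> None:
    outputs = [paths.p(n) for n in ("sim_uniform.csv", "sim_weighted.csv",
                                    "sim_manifest.json")]
    if not force and all(o.exists() for o in outputs):
        log.info("simulate: outputs exist, skipping")
        return
    grid = _grid(cfg)
    mask = _load_mask(cfg, paths)
    field = lag.VelocityField.from_netcdf(paths.p("field.nc"))
    skw = cfg.get("simulate", {})
    sched = lag.ExperimentSchedule(
        t_start_h=0.0, t_end_h=float(field.time_h[-1]),
        cohort_interval_h=skw.get("cohort_interval_h", 168.0),
        spinup_days=skw.get("spinup_days", 183.0),
        max_life_days=skw.get("max_life_days", 365.0),
        dt_h=skw.get("dt_h", 1.0))
    seed = int(cfg.get("seed", 0))
    with xr.open_dataset(paths.p("deploy_kde.nc"),
                                           engine="scipy") as ds:
        kde = dens.DeploymentDensity(
            np.asarray(ds.lon), np.asarray(ds.lat), np.asarray(ds.density),
            (ds.attrs["bandwidth_lon"], ds.attrs["bandwidth_lat"]))
    manifest = {}
    stores = {}
    for scen in ("uniform", "weighted"):
        store = lag.run_experiment(scen, field, mask, sched, grid=grid,
                                   mean_density=skw.get("mean_density", 5),
                                   kde=kde if scen == "weighted" else None,
                                   seed=seed + (0 if scen == "uniform" else 1))
        store.to_dataframe().to_csv(paths.p(f"sim_{scen}.csv"), index=False)
        manifest[scen] = store.manifest
        stores[scen] = store
    manifest["config_hash"] = _hash(cfg)
    paths.p("sim_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                       default=str))
    log.info("simulate: %s", {k: v.get("released_total")
                              for k, v in manifest.items() if isinstance(v, dict)})


def stage_connect(cfg: dict, paths: RunPaths, force: bool = False) -> None:
    outputs = [paths.p(n) for n in ("connectivity_sim.csv",
                                    "lag_density_sim.nc",
                                    "coastal_correlation.json")]
    if not force and all(o.exists() for o in outputs):
        log.info("connect: outputs exist, skipping")
        return
    grid = _grid(cfg)
    mask = _load_mask(cfg, paths)
    field = lag.VelocityField.from_netcdf(paths.p("field.nc"))
    ev = pd.read_csv(paths.p("events.csv"))
    beach_cells = set(ev["cell"].astype(int)) if len(ev) else set()
    skw = cfg.get("simulate", {})
    sched = lag.ExperimentSchedule(
        t_start_h=0.0, t_end_h=float(field.time_h[-1]),
        cohort_interval_h=skw.get("cohort_interval_h", 168.0),
        spinup_days=skw.get("spinup_days", 183.0),
        max_life_days=skw.get("max_life_days", 365.0),
        dt_h=skw.get("dt_h", 1.0))
    seed = int(cfg.get("seed", 0))
    # rebuild the two scenario runs (cheap at demo scale, deterministic)
    with xr.open_dataset(paths.p("deploy_kde.nc"),
                                           engine="scipy") as ds:
        kde = dens.DeploymentDensity(
            np.asarray(ds.lon), np.asarray(ds.lat), np.asarray(ds.density),
            (ds.attrs["bandwidth_lon"], ds.attrs["bandwidth_lat"]))
    region_spec = bch.RegionSpec(**cfg.get("regions", {})) \
        if cfg.get("regions") else bch.RegionSpec()
    result = {}
    with xr.open_dataset(paths.p("dfad_weeks.nc"),
                                           engine="scipy") as ds:
        observed = np.asarray(ds.dfad_weeks, dtype=float)
    coastal = lag.coastal_cell_mask(grid, mask)
    for scen in ("uniform", "weighted"):
        store = lag.run_experiment(scen, field, mask, sched, grid=grid,
                                   mean_density=skw.get("mean_density", 5),
                                   kde=kde if scen == "weighted" else None,
                                   seed=seed + (0 if scen == "uniform" else 1))
        sim_density = lag.mean_daily_cell_counts(store, grid)
        try:
            r, n = lag.coastal_density_correlation(sim_density, observed,
                                                   coastal)
        except ValueError:
            r, n = float("nan"), int(coastal.sum())
        result[scen] = {"pearson_r": r, "n_coastal_cells": n}
        if scen == "weighted" and beach_cells:
            trajs = lag.extract_beaching_trajectories(store, beach_cells, grid)
            if trajs:
                mat = conn.connectivity_matrix(trajs, grid=grid,
                                               region_spec=region_spec)
                mat.to_csv(paths.p("connectivity_sim.csv"), index=False)
                conn.lag_density_maps(trajs, grid=grid).to_netcdf(
                    paths.p("lag_density_sim.nc"), engine="scipy")
    if not paths.p("connectivity_sim.csv").exists():
        paths.p("connectivity_sim.csv").write_text("")
        paths.p("lag_density_sim.nc").write_bytes(b"")
    paths.p("coastal_correlation.json").write_text(json.dumps(result,
                                                              indent=2))
    log.info("connect: %s", result)


_STAGE_FN = {"synth": stage_synth, "clean": stage_clean,
             "detect": stage_detect, "density": stage_density,
             "classify": stage_classify, "simulate": stage_simulate,
             "connect": stage_connect}


def run_all(cfg: dict, out_dir, force: bool = False) -> RunPaths:
    """Run every stage in order, skipping stages whose outputs exist."""
    paths = RunPaths(Path(out_dir))
    manifest = {"config": cfg, "config_hash": _hash(cfg), "stages": STAGES}
    paths.p("manifest.json").write_text(json.dumps(manifest, indent=2,
                                                   default=str))
    for name in STAGES:
        log.info("stage %s", name)
        _STAGE_FN[name](cfg, paths, force=force)
    return paths


def run_stage(name: str, cfg: dict, out_dir, force: bool = False) -> None:
    if name not in _STAGE_FN:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    _STAGE_FN[name](cfg, RunPaths(Path(out_dir)), force=force)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
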