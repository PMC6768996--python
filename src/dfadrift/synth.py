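"""Synthetic study worlds: velocity fields, island land masks and fleet-like
buoy transmission tables with ground truth.

The generator emulates the observational setting of a tropical purse-seine
dFAD fleet: hourly satellite pings, on-board transit phases at vessel speed,
passive drift through a westward equatorial jet with superposed mesoscale
eddies, stranding on islands, recoveries/redeployments and deactivations.
Ground truth (per-ping at-sea/on-board labels, deployments, beachings) is
emitted alongside the data, never inferred.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo import KM_PER_DEG, GridSpec, LandMask, haversine_km, normalize_lon
from .lagrangian import VelocityField, rk4_step

__all__ = [
    "SyntheticWorldConfig",
    "FleetConfig",
    "make_land_mask",
    "gen_velocity_field",
    "solid_body_velocity_field",
    "gen_fleet_tracks",
    "gen_cell_quarter_table",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["buoy_id", "timestamp", "lon", "lat"]

# Buoy state machine codes
_PRE, _DRIFT, _BEACHED, _DONE = 0, 1, 2, 3


@dataclass
class SyntheticWorldConfig:
    """Geometry and dynamics of a synthetic ocean.

    The default dynamics mimic the western-central equatorial Pacific: a
    0.3 m/s westward jet with mesoscale eddies of ~150 km radius.
    """

    grid: GridSpec
    islands: Sequence[tuple] = ()            # (lon, lat, radius_km)
    jet_speed: float = 0.3                   # m/s, westward
    eddy_count: int = 6
    eddy_amplitude: float = 0.15             # m/s peak rotational speed scale
    eddy_radius_km: float = 150.0
    time_span_days: float = 120.0
    field_interval_h: float = 24.0
    field_cell_size: float = 0.25
    mask_cell_size: float = 0.05
    ports: Sequence[tuple] = ()              # (lon, lat)
    rng_seed: int = 0

    def __post_init__(self):
        if self.jet_speed < 0 or self.eddy_amplitude < 0:
            raise ValueError("speeds must be non-negative")
        for lon, lat, _r in self.islands:
            if not self.grid.contains(lon, lat):
                raise ValueError(f"island ({lon}, {lat}) outside grid")


@dataclass
class FleetConfig:
    """Behaviour of a synthetic buoy fleet."""

    n_buoys: int = 100
    transmission_interval_h: float = 1.0
    vessel_speed: float = 5.5                # m/s (~20 km/h) during on-board phases
    deployment_distribution: str = "uniform"  # "uniform" | "hotspot"
    hotspots: Sequence[tuple] = ()           # (lon, lat, sd_deg) Gaussian components
    recovery_probability: float = 0.02       # per day while drifting
    deactivation_probability: float = 0.01   # per day while drifting
    drift_noise_km: float = 0.5              # isotropic process noise per drift step
    predeploy_probability: float = 0.7       # chance of an on-board phase before deployment
    fixed_deployments: Optional[Sequence[tuple]] = None
    span_days: Optional[float] = None        # defaults to the field's span
    n_beached_pings: int = 6                 # stationary pings after stranding
    rng_seed: int = 0

    def __post_init__(self):
        for p in (self.recovery_probability, self.deactivation_probability,
                  self.predeploy_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_buoys < 1:
            raise ValueError("n_buoys must be >= 1")
        if self.deployment_distribution not in ("uniform", "hotspot"):
            raise ValueError("deployment_distribution must be uniform|hotspot")
        if self.deployment_distribution == "hotspot" and not self.hotspots:
            raise ValueError("hotspot distribution needs hotspot components")


def make_land_mask(cfg: SyntheticWorldConfig) -> LandMask:
    """Rasterize circular islands onto a fine boolean mask."""
    grid = cfg.grid.refine(cfg.mask_cell_size)
    lon_c, lat_c = np.meshgrid(grid.lon_centers, grid.lat_centers)
    land = np.zeros(lon_c.shape, dtype=bool)
    for lon, lat, r_km in cfg.islands:
        land |= haversine_km(lon_c, lat_c, normalize_lon(lon), lat) <= r_km
    return LandMask(grid, land, np.asarray(cfg.ports, float).reshape(-1, 2))


def gen_velocity_field(cfg: SyntheticWorldConfig,
                       mask: Optional[LandMask] = None) -> VelocityField:
    """Westward jet plus stream-function eddies, sampled on the field grid.

    Eddies are Gaussian stream-function bumps whose centres are drawn from
    the seeded rng and advected westward with the jet, giving a smoothly
    time-evolving, divergence-controlled field.  u and v are zeroed on land
    cells.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    fgrid = cfg.grid.refine(cfg.field_cell_size)
    lon = fgrid.lon_centers
    lat = fgrid.lat_centers
    time_h = np.arange(0.0, cfg.time_span_days * 24.0 + 1e-9,
                       cfg.field_interval_h)
    lon_g, lat_g = np.meshgrid(lon, lat)

    centers = np.column_stack([
        cfg.grid.lon_min + rng.random(cfg.eddy_count) * (cfg.grid.lon_max - cfg.grid.lon_min),
        cfg.grid.lat_min + rng.random(cfg.eddy_count) * (cfg.grid.lat_max - cfg.grid.lat_min),
    ]) if cfg.eddy_count else np.empty((0, 2))
    spins = rng.choice([-1.0, 1.0], size=cfg.eddy_count)

    jet_deg_per_h = cfg.jet_speed * 3.6 / KM_PER_DEG  # drift of eddy centres
    u = np.empty((len(time_h), len(lat), len(lon)))
    v = np.empty_like(u)
    for it, t in enumerate(time_h):
        ut = np.full(lon_g.shape, -cfg.jet_speed)
        vt = np.zeros(lon_g.shape)
        for (c_lon, c_lat), s in zip(centers, spins):
            c_lon_t = cfg.grid.lon_min + np.mod(
                c_lon - jet_deg_per_h * t - cfg.grid.lon_min,
                cfg.grid.lon_max - cfg.grid.lon_min)
            dx = ((lon_g - c_lon_t + 180.0) % 360.0 - 180.0) * KM_PER_DEG \
                * np.cos(np.radians(lat_g))
            dy = (lat_g - c_lat) * KM_PER_DEG
            r2 = (dx * dx + dy * dy) / cfg.eddy_radius_km ** 2
            env = np.exp(-r2 / 2.0)
            amp = s * cfg.eddy_amplitude * np.e ** 0.5  # peak speed = amplitude
            ut += amp * (dy / cfg.eddy_radius_km) * env
            vt += -amp * (dx / cfg.eddy_radius_km) * env
        u[it], v[it] = ut, vt

    if mask is not None:
        on_land = mask.on_land(lon_g.ravel(), lat_g.ravel()).reshape(lon_g.shape)
        u[:, on_land] = 0.0
        v[:, on_land] = 0.0
    return VelocityField(lon, lat, time_h, u, v)


def solid_body_velocity_field(grid: GridSpec, center_lon: float,
                              center_lat: float, omega_rad_s: float,
                              cell_size: float = 0.25) -> VelocityField:
    """Gridded solid-body-rotation preset (constant-curl verification flow)."""
    from .lagrangian import solid_body_field
    fgrid = grid.refine(cell_size)
    lon_g, lat_g = np.meshgrid(fgrid.lon_centers, fgrid.lat_centers)
    an = solid_body_field(center_lon, center_lat, omega_rad_s)
    u = an.u_fn(0.0, lon_g, lat_g)
    v = an.v_fn(0.0, lon_g, lat_g)
    return VelocityField(fgrid.lon_centers, fgrid.lat_centers, [0.0],
                         u[None], v[None])


# ---------------------------------------------------------------------------
# Fleet simulation
# ---------------------------------------------------------------------------

def _sample_deployments(n, fleet: FleetConfig, grid: GridSpec,
                        mask: Optional[LandMask], rng) -> tuple:
    if fleet.fixed_deployments is not None:
        pts = np.asarray(fleet.fixed_deployments, float)
        reps = int(np.ceil(n / len(pts)))
        pts = np.tile(pts, (reps, 1))[:n]
        return normalize_lon(pts[:, 0]), pts[:, 1]
    lons = np.empty(n)
    lats = np.empty(n)
    filled = 0
    hot = np.asarray(fleet.hotspots, float).reshape(-1, 3) \
        if fleet.deployment_distribution == "hotspot" else None
    for _ in range(500):
        if filled >= n:
            break
        need = n - filled
        if hot is None:
            cand_lon = grid.lon_min + rng.random(need) * (grid.lon_max - grid.lon_min)
            cand_lat = grid.lat_min + rng.random(need) * (grid.lat_max - grid.lat_min)
        else:
            comp = rng.integers(0, len(hot), size=need)
            cand_lon = normalize_lon(hot[comp, 0]) + rng.normal(0, hot[comp, 2])
            cand_lat = hot[comp, 1] + rng.normal(0, hot[comp, 2])
        ok = grid.contains(cand_lon, cand_lat)
        if mask is not None:
            ok &= ~mask.on_land(cand_lon, cand_lat)
        k = int(ok.sum())
        lons[filled:filled + k] = normalize_lon(cand_lon[ok])
        lats[filled:filled + k] = cand_lat[ok]
        filled += k
    if filled < n:
        raise RuntimeError("could not sample enough sea deployment positions")
    return lons, lats


def gen_fleet_tracks(fleet: FleetConfig, field: VelocityField,
                     mask: Optional[LandMask], grid: GridSpec,
                     t0: pd.Timestamp = pd.Timestamp("2016-01-01")) -> tuple:
    """Simulate a buoy fleet; returns (transmissions, truth_labels, truth_events).

    transmissions: buoy_id, timestamp, lon, lat (one row per ping).
    truth_labels: same keying plus label (at_sea|on_board) and event_type.
    truth_events: buoy_id, event (deployment|beaching|recovery|deactivation),
    time, lon, lat, segment_index.
    """
    rng = np.random.default_rng(fleet.rng_seed)
    n = fleet.n_buoys
    dt = fleet.transmission_interval_h
    span_h = (fleet.span_days if fleet.span_days is not None
              else field.time_h[-1] / 24.0) * 24.0
    n_steps = int(round(span_h / dt))

    p_step = lambda p_day: 1.0 - (1.0 - p_day) ** (dt / 24.0)
    p_recover = p_step(fleet.recovery_probability)
    p_deactivate = p_step(fleet.deactivation_probability)

    # per-buoy state
    lon = np.zeros(n)
    lat = np.zeros(n)
    tgt_lon, tgt_lat = _sample_deployments(n, fleet, grid, mask, rng)
    state = np.full(n, _PRE, dtype=int)
    seg_idx = np.zeros(n, dtype=int)       # current drift-segment ordinal (1-based once deployed)
    beach_left = np.zeros(n, dtype=int)
    start_step = rng.integers(0, max(int(n_steps * 0.3), 1), size=n)

    predeploy = rng.random(n) < fleet.predeploy_probability
    needs_deploy_ping = np.zeros(n, dtype=bool)
    for i in range(n):
        if predeploy[i]:
            if mask is not None and len(mask.ports):
                p = mask.ports[rng.integers(0, len(mask.ports))]
                lon[i], lat[i] = p[0], p[1]
            else:
                # start a transit leg ~150 km from the deployment point
                ang = rng.random() * 2 * np.pi
                lon[i] = tgt_lon[i] + 150.0 * np.cos(ang) / (
                    KM_PER_DEG * np.cos(np.radians(tgt_lat[i])))
                lat[i] = np.clip(tgt_lat[i] + 150.0 * np.sin(ang) / KM_PER_DEG,
                                 grid.lat_min, grid.lat_max - 1e-6)
                lon[i] = normalize_lon(lon[i])
        else:
            lon[i], lat[i] = tgt_lon[i], tgt_lat[i]
            state[i] = _DRIFT
            seg_idx[i] = 1
            needs_deploy_ping[i] = True

    rows_step, rows_buoy = [], []
    rows_lon, rows_lat, rows_label, rows_event = [], [], [], []
    events = []

    def emit(ids, step, labels, event_codes):
        rows_buoy.append(ids)
        rows_step.append(np.full(len(ids), step))
        rows_lon.append(lon[ids].copy())
        rows_lat.append(lat[ids].copy())
        rows_label.append(labels)
        rows_event.append(event_codes)

    vessel_kmh = fleet.vessel_speed * 3.6
    noise_deg = fleet.drift_noise_km / KM_PER_DEG

    # beached buoys keep transmitting their stranding position for a few
    # pings even when that crosses the end of the drift window
    for step in range(n_steps + fleet.n_beached_pings):
        in_span = step < n_steps
        active = (state != _DONE) & (start_step <= step)
        if not in_span:
            active &= state == _BEACHED
        if not active.any():
            continue
        labels = np.full(n, "", dtype=object)
        event_codes = np.full(n, "", dtype=object)

        # --- first ping of buoys deployed without a transit phase -----------
        fresh = active & needs_deploy_ping
        if fresh.any():
            ids = np.nonzero(fresh)[0]
            labels[ids] = "at_sea"
            event_codes[ids] = "deployment"
            needs_deploy_ping[ids] = False
            for i in ids:
                events.append((i, "deployment", step, lon[i], lat[i], seg_idx[i]))

        # --- on-board transit toward deployment target ---------------------
        pre = active & (state == _PRE)
        if pre.any():
            ids = np.nonzero(pre)[0]
            d = haversine_km(lon[ids], lat[ids], tgt_lon[ids], tgt_lat[ids])
            step_km = vessel_kmh * dt
            arrive = d <= step_km
            far = ids[~arrive]
            if len(far):
                f = step_km / d[~arrive]
                dlat = (tgt_lat[far] - lat[far]) * f
                dlon = ((tgt_lon[far] - lon[far] + 180.0) % 360.0 - 180.0) * f
                lon[far] = normalize_lon(lon[far] + dlon)
                lat[far] += dlat
                labels[far] = "on_board"
            hit = ids[arrive]
            if len(hit):
                lon[hit], lat[hit] = tgt_lon[hit], tgt_lat[hit]
                state[hit] = _DRIFT
                seg_idx[hit] += 1
                labels[hit] = "at_sea"
                event_codes[hit] = "deployment"
                for i in hit:
                    events.append((i, "deployment", step, lon[i], lat[i], seg_idx[i]))

        # --- passive drift --------------------------------------------------
        drifting = active & (state == _DRIFT) & (labels == "")
        if drifting.any():
            ids = np.nonzero(drifting)[0]
            t_h = step * dt
            new_lon, new_lat = rk4_step(field, t_h, lon[ids], lat[ids], dt)
            if fleet.drift_noise_km > 0:
                new_lat = new_lat + rng.normal(0, noise_deg, len(ids))
                new_lon = normalize_lon(
                    new_lon + rng.normal(0, noise_deg, len(ids))
                    / np.cos(np.radians(new_lat)))
            outside = ~grid.contains(new_lon, new_lat)
            grounded = np.zeros(len(ids), dtype=bool)
            if mask is not None:
                grounded = mask.on_land(new_lon, new_lat) & ~outside
            ok = ~grounded & ~outside
            lon[ids[ok]] = new_lon[ok]
            lat[ids[ok]] = new_lat[ok]
            labels[ids] = "at_sea"
            # stranding: halt at last sea position, keep pinging there
            hit = ids[grounded]
            if len(hit):
                state[hit] = _BEACHED
                beach_left[hit] = fleet.n_beached_pings
                event_codes[hit] = "beaching"
                for i in hit:
                    events.append((i, "beaching", step, lon[i], lat[i], seg_idx[i]))
            # leaving the domain: deactivate silently after this ping
            left = ids[outside]
            if len(left):
                state[left] = _DONE
            # recovery / deactivation draws for the rest
            rest = ids[ok]
            if len(rest):
                r = rng.random(len(rest))
                rec = rest[r < p_recover]
                dea = rest[(r >= p_recover) & (r < p_recover + p_deactivate)]
                if len(rec):
                    state[rec] = _PRE
                    labels[rec] = "on_board"
                    event_codes[rec] = "recovery"
                    nl, nt = _sample_deployments(len(rec), fleet, grid, mask, rng)
                    tgt_lon[rec], tgt_lat[rec] = nl, nt
                    for i in rec:
                        events.append((i, "recovery", step, lon[i], lat[i], seg_idx[i]))
                if len(dea):
                    state[dea] = _DONE
                    event_codes[dea] = "deactivation"
                    for i in dea:
                        events.append((i, "deactivation", step, lon[i], lat[i], seg_idx[i]))

        # --- beached: stationary pings, then silence ------------------------
        beached = active & (state == _BEACHED) & (labels == "")
        if beached.any():
            ids = np.nonzero(beached)[0]
            labels[ids] = "at_sea"
            beach_left[ids] -= 1
            done = ids[beach_left[ids] <= 0]
            state[done] = _DONE

        got = np.nonzero(labels != "")[0]
        emit(got, step, labels[got], event_codes[got])

    steps = np.concatenate(rows_step) if rows_step else np.empty(0, int)
    ids = np.concatenate(rows_buoy) if rows_buoy else np.empty(0, int)
    ts = t0 + pd.to_timedelta(steps * dt, unit="h")
    tracks = pd.DataFrame({
        "buoy_id": [f"B{int(i):05d}" for i in ids],
        "timestamp": ts,
        "lon": np.concatenate(rows_lon) if rows_lon else [],
        "lat": np.concatenate(rows_lat) if rows_lat else [],
    })
    truth_labels = tracks.copy()
    truth_labels["label"] = np.concatenate(rows_label) if rows_label else []
    truth_labels["event_type"] = np.concatenate(rows_event) if rows_event else []
    order = np.lexsort((steps, ids))
    tracks = tracks.iloc[order].reset_index(drop=True)
    truth_labels = truth_labels.iloc[order].reset_index(drop=True)

    truth_events = pd.DataFrame(
        events, columns=["buoy", "event", "step", "lon", "lat", "segment_index"])
    truth_events["buoy_id"] = [f"B{int(i):05d}" for i in truth_events["buoy"]]
    truth_events["time"] = t0 + pd.to_timedelta(truth_events["step"] * dt, unit="h")
    truth_events = truth_events[["buoy_id", "event", "time", "lon", "lat",
                                 "segment_index"]].sort_values(
        ["buoy_id", "time"]).reset_index(drop=True)
    return tracks, truth_labels, truth_events


# ---------------------------------------------------------------------------
# Synthetic (cell, quarter) tables for the residual classifier
# ---------------------------------------------------------------------------

def gen_cell_quarter_table(n: int = 200, *, intercept: float = 2.0,
                           slope: float = 0.5,
                           quarter_offsets=(0.0, 3.0, 0.0, -3.0),
                           sigma: float = 0.5, outlier_fraction: float = 0.1,
                           outlier_sd: float = 5.0, rng_seed: int = 0):
    """Simulated (cell, quarter) beaching records with planted outlier cells.

    Counts follow ``intercept + slope * density + quarter offset + noise``.
    A fraction of high-density records is planted as anomalies whose count
    deviates from the regression surface by exactly +/- `outlier_sd` * sigma
    (the anomaly replaces the noise term), giving known beaching-prone and
    beaching-resilient sets.  Returns (records, prone_idx, resilient_idx).
    """
    rng = np.random.default_rng(rng_seed)
    n_out = int(outlier_fraction * n)
    density = rng.uniform(0.0, 100.0, n)
    quarter = rng.integers(1, 5, n)
    offs = np.asarray(quarter_offsets, dtype=float)[quarter - 1]
    mu = intercept + slope * density + offs
    y = mu + rng.normal(0.0, sigma, n)
    prone: set = set()
    resilient: set = set()
    if n_out:
        # plant on high-density records so the resilient rule (which demands
        # high local density) can recover them
        hi = np.argsort(density)[-2 * n_out:]
        pick = rng.permutation(hi)
        prone = set(int(i) for i in pick[:n_out])
        resilient = set(int(i) for i in pick[n_out:2 * n_out])
        for i in prone:
            y[i] = mu[i] + outlier_sd * sigma
        for i in resilient:
            y[i] = mu[i] - outlier_sd * sigma
    records = pd.DataFrame({"cell": np.arange(n), "quarter": quarter,
                            "n_beaching": y, "density": density})
    return records, prone, resilient
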