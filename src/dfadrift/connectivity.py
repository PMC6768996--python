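"""Source-sink connectivity of beaching trajectories.

Each beaching trajectory carries its source (deployment or release)
position and its total drift time to the beaching cell.  Drift times fall
into fixed bins (<1, 1-3, 3-6, 6-9, >9 months with a 30.44-day month);
sources are grouped into deployment hotspots or geographic regions.  The
connectivity matrix reports, for each (beaching region, lag bin), the
percentage of trajectories originating in each source region.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .beaching import RegionSpec, assign_region
from .density import Hotspots
from .geo import GridSpec, normalize_lon
from .lagrangian import BeachingTrajectory

__all__ = [
    "MONTH_DAYS",
    "LagBinSpec",
    "position_at_lag",
    "source_region_of",
    "connectivity_matrix",
    "lag_density_maps",
    "observed_beaching_trajectory",
]

#: Mean month length in days; keeps lag bins independent of release dates.
MONTH_DAYS = 30.44


@dataclass(frozen=True)
class LagBinSpec:
    """Ordered drift-time bins in days before beaching, partitioning (0, inf)."""

    edges_days: Sequence[float] = (MONTH_DAYS, 3 * MONTH_DAYS, 6 * MONTH_DAYS,
                                   9 * MONTH_DAYS)
    labels: Sequence[str] = ("<1 m", "1-3 m", "3-6 m", "6-9 m", ">9 m")

    def __post_init__(self):
        e = np.asarray(self.edges_days, dtype=float)
        if np.any(np.diff(e) <= 0) or np.any(e <= 0):
            raise ValueError("edges must be positive and strictly increasing")
        if len(self.labels) != len(e) + 1:
            raise ValueError("need len(edges) + 1 labels")

    def bin_of(self, drift_days):
        """Index of the bin containing each drift time."""
        return np.searchsorted(np.asarray(self.edges_days), drift_days,
                               side="left")

    def label_of(self, drift_days):
        idx = np.atleast_1d(self.bin_of(drift_days))
        lab = np.asarray(self.labels, dtype=object)[idx]
        return str(lab[0]) if np.isscalar(drift_days) else lab


def position_at_lag(traj: BeachingTrajectory, lag_days: float):
    """Position `lag_days` before beaching-cell entry, linearly interpolated
    between recorded fixes; None if the trajectory does not reach that far
    back.  Negative lags are an error."""
    if lag_days < 0:
        raise ValueError("lag must be non-negative")
    target = traj.entry_time_h - lag_days * 24.0
    times = traj.times_h
    ok = np.isfinite(traj.lons)
    times, lons, lats = times[ok], traj.lons[ok], traj.lats[ok]
    if len(times) == 0 or target < times[0] - 1e-9:
        return None
    target = min(target, times[-1])
    # unwrap longitudes so interpolation crosses the antimeridian cleanly
    lon_u = np.concatenate([[lons[0]], lons[0] + np.cumsum(
        (np.diff(lons) + 180.0) % 360.0 - 180.0)])
    lon = np.interp(target, times, lon_u)
    lat = np.interp(target, times, lats)
    return float(normalize_lon(lon)), float(lat)


def source_region_of(lon, lat, hotspots: Optional[Hotspots],
                     region_spec: RegionSpec = RegionSpec()) -> str:
    """Hotspot label ("hotspot_k") when the position falls in a hotspot
    cell, otherwise the geographic region label."""
    if hotspots is not None:
        flat = hotspots.grid.flat_cell_of(lon, lat, strict=False)
        if np.ndim(flat) == 0 and flat >= 0:
            comp = hotspots.label_of_cell(int(flat))
            if comp > 0:
                return f"hotspot_{comp}"
    return assign_region(lon, lat, region_spec)


def _beaching_region(traj: BeachingTrajectory, grid: GridSpec,
                     region_spec: RegionSpec) -> str:
    lon, lat = grid.flat_center(traj.cell)
    return assign_region(float(lon), float(lat), region_spec)


def connectivity_matrix(trajs: Sequence[BeachingTrajectory],
                        lag_spec: LagBinSpec = LagBinSpec(),
                        hotspots: Optional[Hotspots] = None,
                        region_spec: RegionSpec = RegionSpec(),
                        grid: Optional[GridSpec] = None,
                        domain: Optional[GridSpec] = None) -> pd.DataFrame:
    """Tidy percentage connectivity matrix.

    One row per (beaching_region, lag_bin, source_region) with the count and
    the percentage over source regions within that (beaching_region,
    lag_bin).  Sources outside the study domain fall into an "external"
    column rather than being dropped.
    """
    if not len(trajs):
        raise ValueError("need at least one beaching trajectory")
    if grid is None:
        raise ValueError("a beaching-cell grid is required")
    rows = []
    for tr in trajs:
        lag = lag_spec.label_of(float(tr.drift_days))
        beach_reg = _beaching_region(tr, grid, region_spec)
        src_lon, src_lat = tr.source_lon, tr.source_lat
        dom = domain if domain is not None else grid
        if not bool(np.atleast_1d(dom.contains(src_lon, src_lat))[0]):
            src = "external"
        else:
            src = source_region_of(src_lon, src_lat, hotspots, region_spec)
        rows.append((beach_reg, lag, src))
    df = pd.DataFrame(rows, columns=["beaching_region", "lag_bin",
                                     "source_region"])
    counts = (df.groupby(["beaching_region", "lag_bin", "source_region"])
              .size().rename("count").reset_index())
    totals = counts.groupby(["beaching_region", "lag_bin"])["count"] \
        .transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    counts["lag_bin"] = pd.Categorical(counts["lag_bin"],
                                       categories=list(lag_spec.labels),
                                       ordered=True)
    return counts.sort_values(["beaching_region", "lag_bin",
                               "source_region"]).reset_index(drop=True)


def lag_density_maps(trajs: Sequence[BeachingTrajectory],
                     lag_spec: LagBinSpec = LagBinSpec(),
                     grid: Optional[GridSpec] = None) -> xr.Dataset:
    """Spatial probability density of pre-beaching positions per lag bin.

    For each bin, recorded positions whose lag before entry falls in the bin
    are histogrammed on the grid and normalized to sum to 1; empty bins are
    flagged in ``empty_bins``.
    """
    if grid is None:
        raise ValueError("a grid is required")
    fields = np.zeros((len(lag_spec.labels), grid.n_lat, grid.n_lon))
    for tr in trajs:
        ok = np.isfinite(tr.lons)
        lags = (tr.entry_time_h - tr.times_h[ok]) / 24.0
        use = lags > 0
        if tr.drift_days == 0 and len(tr.times_h) == 1:
            # a trajectory beaching at release contributes its single fix
            lags, use = np.array([0.0]), np.array([True])
        flat = grid.flat_cell_of(tr.lons[ok][use], tr.lats[ok][use],
                                 strict=False)
        bins = lag_spec.bin_of(np.maximum(lags[use], 1e-9))
        good = flat >= 0
        np.add.at(fields, (bins[good], flat[good] // grid.n_lon,
                           flat[good] % grid.n_lon), 1.0)
    sums = fields.sum(axis=(1, 2))
    empty = sums == 0
    with np.errstate(invalid="ignore"):
        fields = np.where(empty[:, None, None], 0.0,
                          fields / np.maximum(sums, 1.0)[:, None, None])
    ds = xr.Dataset(
        {"density": (("lag_bin", "lat", "lon"), fields),
         "empty_bins": (("lag_bin",), empty)},
        coords={"lag_bin": list(lag_spec.labels),
                "lat": grid.lat_centers, "lon": grid.lon_centers})
    return ds


def observed_beaching_trajectory(segment, event, grid: GridSpec):
    """Build a BeachingTrajectory from an observed drift segment and its
    detected beaching event; the deployment is the source position."""
    t0 = np.asarray(segment.times, dtype="datetime64[ns]")[0]
    times_h = (np.asarray(segment.times, dtype="datetime64[ns]") - t0) \
        / np.timedelta64(1, "h")
    entry_h = float((np.datetime64(event.time) - t0) / np.timedelta64(1, "h"))
    return BeachingTrajectory(
        particle_id=f"{segment.buoy_id}/{segment.segment_index}",
        cell=event.cell, entry_time_h=entry_h, release_time_h=0.0,
        times_h=times_h, lons=np.asarray(segment.lons, float),
        lats=np.asarray(segment.lats, float))
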