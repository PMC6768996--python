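"""Rule-based beaching detection and aggregation onto 1-degree coastal cells.

A drift segment ends in a beaching event when (i) its last position lies
within `beach_dist_km` of shore, (ii) it is farther than `port_excl_km`
from every major port, and (iii) its last `n_last` transmissions are
pairwise co-located within `same_loc_tol_km`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .cleaning import DriftSegment
from .geo import GridSpec, LandMask, haversine_km, normalize_lon

__all__ = [
    "BeachingEvent",
    "BeachingCells",
    "RegionSpec",
    "detect_beaching",
    "detect_all",
    "aggregate_beaching_cells",
    "assign_region",
    "events_to_dataframe",
    "events_to_geojson",
    "counts_to_dataset",
]


@dataclass
class BeachingEvent:
    """A terminal stranding of one drift segment, tied to a 1-deg cell."""

    buoy_id: str
    segment_index: int
    lon: float
    lat: float
    time: pd.Timestamp
    cell: int
    quarter: int
    year: int


def detect_beaching(segment: DriftSegment, mask: LandMask, grid: GridSpec,
                    beach_dist_km: float = 10.0, port_excl_km: float = 10.0,
                    n_last: int = 3,
                    same_loc_tol_km: float = 1.0) -> Optional[BeachingEvent]:
    """Apply the beaching rule to one drift segment.

    Returns the event (timed at the last transmission) or None.  Segments
    shorter than `n_last` cannot be assessed and return None.
    """
    if len(segment) < n_last:
        return None
    lon_f = float(segment.lons[-1])
    lat_f = float(segment.lats[-1])
    if mask.distance_to_shore_km(lon_f, lat_f) > beach_dist_km:
        return None
    if len(mask.ports) and mask.distance_to_port_km(lon_f, lat_f) <= port_excl_km:
        return None
    tail_lon = segment.lons[-n_last:]
    tail_lat = segment.lats[-n_last:]
    pairwise = haversine_km(tail_lon[:, None], tail_lat[:, None],
                            tail_lon[None, :], tail_lat[None, :])
    if pairwise.max() > same_loc_tol_km:
        return None
    t = pd.Timestamp(segment.times[-1])
    cell = int(grid.flat_cell_of(lon_f, lat_f, strict=False))
    if cell < 0:
        return None
    return BeachingEvent(segment.buoy_id, segment.segment_index,
                         normalize_lon(lon_f), lat_f, t, cell,
                         int(t.quarter), int(t.year))


def detect_all(segments: Sequence[DriftSegment], mask: LandMask,
               grid: GridSpec, **kwargs):
    """Run the rule over all segments; returns (events, skipped_log)."""
    events = []
    skipped = []
    n_last = kwargs.get("n_last", 3)
    for seg in segments:
        if len(seg) < n_last:
            skipped.append({"buoy_id": seg.buoy_id,
                            "segment_index": seg.segment_index,
                            "reason": "shorter_than_n_last"})
            continue
        ev = detect_beaching(seg, mask, grid, **kwargs)
        if ev is not None:
            events.append(ev)
    return events, pd.DataFrame(skipped, columns=["buoy_id", "segment_index",
                                                  "reason"])


@dataclass
class BeachingCells:
    """Beaching events grouped by 1-deg cell, with per-quarter counts."""

    grid: GridSpec
    counts: pd.DataFrame          # cell, col, row, lon, lat, n_events, q1..q4
    events_by_cell: dict

    @property
    def cells(self) -> set:
        return set(self.counts["cell"].astype(int))

    @property
    def total_events(self) -> int:
        return int(self.counts["n_events"].sum())


def aggregate_beaching_cells(events: Sequence[BeachingEvent],
                             grid: GridSpec) -> BeachingCells:
    """Group events into beaching cells (1-deg cells with >= 1 event)."""
    by_cell: dict = {}
    for ev in events:
        by_cell.setdefault(ev.cell, []).append(ev)
    rows = []
    for cell, evs in sorted(by_cell.items()):
        lon, lat = grid.flat_center(cell)
        row = {"cell": cell, "col": cell % grid.n_lon, "row": cell // grid.n_lon,
               "lon": float(lon), "lat": float(lat), "n_events": len(evs)}
        for q in range(1, 5):
            row[f"q{q}"] = sum(1 for e in evs if e.quarter == q)
        rows.append(row)
    counts = pd.DataFrame(rows, columns=["cell", "col", "row", "lon", "lat",
                                         "n_events", "q1", "q2", "q3", "q4"])
    return BeachingCells(grid, counts, by_cell)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """Geographic regions: one northern region above `north_lat` (strictly),
    and longitude bands south of it.

    The study default is north (>0N), southwest (<175E) and southeast
    (>=175E).  Synthetic worlds may configure more bands.
    """

    north_lat: float = 0.0
    lon_edges: Sequence[float] = (175.0,)
    south_labels: Sequence[str] = ("southwest", "southeast")
    north_label: str = "north"

    def __post_init__(self):
        if len(self.south_labels) != len(self.lon_edges) + 1:
            raise ValueError("need len(lon_edges) + 1 south labels")

    @property
    def labels(self) -> list:
        return [self.north_label, *self.south_labels]


def assign_region(lon, lat, spec: RegionSpec = RegionSpec()):
    """Region label of a position: north if lat > north_lat (strict), else
    the longitude band (band edges belong to the eastern band)."""
    lon = normalize_lon(np.asarray(lon, dtype=float))
    lat = np.asarray(lat, dtype=float)
    scalar = lon.ndim == 0
    lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
    edges = normalize_lon(np.asarray(spec.lon_edges, dtype=float))
    band = np.searchsorted(edges, lon, side="right")
    out = np.asarray(spec.south_labels, dtype=object)[band]
    out = np.where(lat > spec.north_lat, spec.north_label, out)
    return str(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def events_to_dataframe(events: Sequence[BeachingEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "buoy_id": e.buoy_id, "segment_index": e.segment_index,
        "lon": e.lon, "lat": e.lat, "time": e.time, "cell": e.cell,
        "quarter": e.quarter, "year": e.year} for e in events],
        columns=["buoy_id", "segment_index", "lon", "lat", "time", "cell",
                 "quarter", "year"])


def events_to_geojson(events: Sequence[BeachingEvent]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [{
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [((e.lon + 180.0) % 360.0) - 180.0, e.lat]},
            "properties": {"buoy_id": e.buoy_id,
                           "segment_index": e.segment_index,
                           "time": str(e.time), "cell": e.cell,
                           "quarter": e.quarter, "year": e.year},
        } for e in events],
    }


def counts_to_dataset(cells: BeachingCells) -> xr.Dataset:
    """Per-cell event counts as a gridded field."""
    grid = cells.grid
    arr = np.zeros((grid.n_lat, grid.n_lon))
    for _, r in cells.counts.iterrows():
        arr[int(r["row"]), int(r["col"])] = r["n_events"]
    return xr.Dataset({"n_beaching": (("lat", "lon"), arr)},
                      coords={"lon": grid.lon_centers, "lat": grid.lat_centers})
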