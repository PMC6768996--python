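"""Geographic primitives: great-circle distances, the 1-degree analysis grid,
rasterized land masks with distance-to-shore and distance-to-port fields.

All longitudes are normalized internally to [0, 360) so that study domains
crossing the antimeridian (e.g. 130E-140W) map onto a contiguous axis.
Input and output in [-180, 180] is accepted everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr
from scipy.spatial import cKDTree

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG",
    "DomainError",
    "GeoPoint",
    "GridSpec",
    "LandMask",
    "normalize_lon",
    "haversine_km",
    "initial_bearing_deg",
    "read_ports",
    "write_ports",
]

#: Fixed spherical Earth radius, km.  All distance thresholds in the pipeline
#: (10 km beaching rule, port exclusion, same-location tolerance) are defined
#: against this radius so results are bit-reproducible.
EARTH_RADIUS_KM = 6371.0
#: Arc length of one degree of latitude, km.
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


class DomainError(ValueError):
    """A point fell outside the grid domain."""


def normalize_lon(lon):
    """Normalize longitudes to [0, 360)."""
    return np.mod(lon, 360.0)


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Fully vectorized; broadcasts over array inputs.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


@dataclass(frozen=True)
class GeoPoint:
    """A longitude/latitude position; lon stored normalized to [0, 360)."""

    lon: float
    lat: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", float(self.lon) % 360.0)
        object.__setattr__(self, "lat", float(self.lat))

    def distance_km(self, other: "GeoPoint") -> float:
        return float(haversine_km(self.lon, self.lat, other.lon, other.lat))


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid with half-open cells [edge, edge + size).

    Cell indexing is (col, row) from the (lon_min, lat_min) corner; flat
    indices are row-major: ``flat = row * n_lon + col``.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float = 1.0

    def __post_init__(self):
        lo = float(self.lon_min) % 360.0
        hi = float(self.lon_max) % 360.0
        if hi <= lo:
            hi += 360.0
        object.__setattr__(self, "lon_min", lo)
        object.__setattr__(self, "lon_max", hi)
        for name, n in (("lon", self.n_lon), ("lat", self.n_lat)):
            span = (hi - lo) if name == "lon" else (self.lat_max - self.lat_min)
            if abs(span / self.cell_size - n) > 1e-6:
                raise ValueError(f"{name} span {span} is not an integer number "
                                 f"of {self.cell_size} deg cells")
        if self.lat_max <= self.lat_min:
            raise ValueError("lat_max must exceed lat_min")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.cell_size * np.arange(self.n_lon + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.cell_size * np.arange(self.n_lat + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell_size * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell_size * (np.arange(self.n_lat) + 0.5)

    def _query_lon(self, lon):
        q = normalize_lon(np.asarray(lon, dtype=float))
        return np.where(q < self.lon_min, q + 360.0, q)

    def contains(self, lon, lat):
        q = self._query_lon(lon)
        lat = np.asarray(lat, dtype=float)
        return (q >= self.lon_min) & (q < self.lon_max) & \
               (lat >= self.lat_min) & (lat < self.lat_max)

    def cell_of(self, lon, lat):
        """Map positions to (col, row) indices; raises DomainError outside."""
        q = self._query_lon(lon)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside))
            raise DomainError(f"{bad.size} point(s) outside grid domain")
        col = np.floor((q - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        # guard against edge-of-domain float roundoff
        col = np.clip(col, 0, self.n_lon - 1)
        row = np.clip(row, 0, self.n_lat - 1)
        return col, row

    def flat_cell_of(self, lon, lat, strict: bool = True):
        """Row-major flat cell index; -1 for out-of-domain when strict=False."""
        if strict:
            col, row = self.cell_of(lon, lat)
            return row * self.n_lon + col
        q = self._query_lon(lon)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        col = np.clip(np.floor((q - self.lon_min) / self.cell_size).astype(int),
                      0, self.n_lon - 1)
        row = np.clip(np.floor((lat - self.lat_min) / self.cell_size).astype(int),
                      0, self.n_lat - 1)
        flat = row * self.n_lon + col
        return np.where(inside, flat, -1)

    def cell_center(self, col, row):
        lon = self.lon_min + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.lat_min + (np.asarray(row) + 0.5) * self.cell_size
        return normalize_lon(lon), lat

    def flat_center(self, flat):
        flat = np.asarray(flat)
        return self.cell_center(flat % self.n_lon, flat // self.n_lon)

    def refine(self, cell_size: float) -> "GridSpec":
        """Same bounds at a finer (or coarser) resolution."""
        return GridSpec(self.lon_min, self.lon_max, self.lat_min, self.lat_max,
                        cell_size)


def _unit_xyz(lon, lat):
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


@dataclass
class LandMask:
    """Boolean land raster on a (possibly fine) GridSpec, plus major ports.

    Distance to shore is computed against land-cell centers minus half a cell
    diagonal (floored at zero), a raster stand-in for a vector coastline.
    """

    grid: GridSpec
    is_land: np.ndarray  # (n_lat, n_lon) bool
    ports: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        self.is_land = np.asarray(self.is_land, dtype=bool)
        if self.is_land.shape != (self.grid.n_lat, self.grid.n_lon):
            raise ValueError("is_land shape does not match grid")
        if self.is_land.all():
            raise ValueError("mask has no sea cells")
        self.ports = np.asarray(self.ports, dtype=float).reshape(-1, 2)
        if len(self.ports):
            self.ports[:, 0] = normalize_lon(self.ports[:, 0])
        self._tree = None

    # -- land lookup ------------------------------------------------------
    def on_land(self, lon, lat):
        """True where a position falls in a land cell; out-of-domain is sea."""
        inside = self.grid.contains(lon, lat)
        out = np.zeros(np.shape(inside) or (), dtype=bool)
        if not np.any(inside):
            return out if out.shape else bool(out)
        lon_a = np.atleast_1d(np.asarray(lon, dtype=float))
        lat_a = np.atleast_1d(np.asarray(lat, dtype=float))
        ins = np.atleast_1d(inside)
        col, row = self.grid.cell_of(lon_a[ins], lat_a[ins])
        res = np.atleast_1d(out)
        res[ins] = self.is_land[row, col]
        return res.reshape(np.shape(inside)) if np.shape(inside) else bool(res[0])

    @property
    def half_diagonal_km(self) -> float:
        return self.grid.cell_size * KM_PER_DEG * np.sqrt(2.0) / 2.0

    def _land_tree(self):
        if self._tree is None:
            rows, cols = np.nonzero(self.is_land)
            if rows.size == 0:
                self._tree = False
            else:
                lon, lat = self.grid.cell_center(cols, rows)
                self._tree = cKDTree(_unit_xyz(lon, lat))
        return self._tree

    def distance_to_shore_km(self, lon, lat):
        """Great-circle distance to the nearest land-cell boundary representative.

        Points on land return 0; an all-sea mask returns +inf.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        scalar = lon.ndim == 0
        lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
        tree = self._land_tree()
        if tree is False:
            d = np.full(lon.shape, np.inf)
            return float(d[0]) if scalar else d
        chord, _ = tree.query(_unit_xyz(lon, lat))
        arc = EARTH_RADIUS_KM * 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
        d = np.maximum(arc - self.half_diagonal_km, 0.0)
        d = np.where(self.on_land(lon, lat), 0.0, d)
        return float(d[0]) if scalar else d

    def distance_to_port_km(self, lon, lat, cap_km: float = 20000.0):
        """Distance to nearest major port; `cap_km` when no ports are defined."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        scalar = lon.ndim == 0
        lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
        if len(self.ports) == 0:
            d = np.full(lon.shape, cap_km)
        else:
            d = haversine_km(lon[:, None], lat[:, None],
                             self.ports[None, :, 0], self.ports[None, :, 1]).min(axis=1)
            d = np.minimum(d, cap_km)
        return float(d[0]) if scalar else d

    # -- aggregation helpers ----------------------------------------------
    def land_fraction(self, coarse: GridSpec) -> np.ndarray:
        """Fraction of each coarse cell covered by land cells of this mask."""
        lon_c, lat_c = np.meshgrid(self.grid.lon_centers, self.grid.lat_centers)
        flat = coarse.flat_cell_of(lon_c.ravel(), lat_c.ravel(), strict=False)
        ok = flat >= 0
        land = self.is_land.ravel()[ok]
        counts = np.bincount(flat[ok], minlength=coarse.n_cells).astype(float)
        hits = np.bincount(flat[ok], weights=land.astype(float),
                           minlength=coarse.n_cells)
        with np.errstate(invalid="ignore"):
            frac = np.where(counts > 0, hits / np.maximum(counts, 1), 0.0)
        return frac.reshape(coarse.n_lat, coarse.n_lon)

    # -- I/O ---------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"land": (("lat", "lon"), self.is_land.astype("i1"))},
            coords={"lon": self.grid.lon_centers, "lat": self.grid.lat_centers},
        )
        ds.attrs["cell_size"] = self.grid.cell_size
        ds.attrs["bounds"] = [self.grid.lon_min, self.grid.lon_max,
                              self.grid.lat_min, self.grid.lat_max]
        return ds

    def to_netcdf(self, path):
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, ports=None) -> "LandMask":
        size = float(ds.attrs.get("cell_size",
                                  float(ds.lon[1] - ds.lon[0]) if ds.lon.size > 1 else 1.0))
        lon = np.asarray(ds.lon)
        lat = np.asarray(ds.lat)
        grid = GridSpec(lon[0] - size / 2, lon[-1] + size / 2,
                        lat[0] - size / 2, lat[-1] + size / 2, size)
        return cls(grid, np.asarray(ds["land"]).astype(bool),
                   ports if ports is not None else np.empty((0, 2)))

    @classmethod
    def from_netcdf(cls, path, ports=None) -> "LandMask":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load(), ports)


def read_ports(path) -> np.ndarray:
    """Read ports from a 2-column (lon lat) delimited text file."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.size == 0:
        return np.empty((0, 2))
    return arr[:, :2]


def write_ports(path, ports: np.ndarray) -> None:
    np.savetxt(path, np.asarray(ports, dtype=float).reshape(-1, 2),
               fmt="%.6f", header="lon lat")
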