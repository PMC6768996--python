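"""Observed dFAD density and deployment hotspots.

Two density products: (i) a standardized per-cell count of dFAD-weeks —
distinct (buoy, ISO week) pairs with at least one at-sea transmission in a
1-degree cell — and (ii) a 2D Gaussian product-kernel density of deployment
positions evaluated on a fine lattice, from which hotspot cells are the
1-degree cells exceeding the 95th percentile of all cell values.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .geo import GridSpec, normalize_lon

__all__ = [
    "CellDensityField",
    "DeploymentDensity",
    "Hotspots",
    "standardized_density",
    "nrd_bandwidth",
    "deployment_kde",
    "cell_mean_density",
    "hotspot_cells",
]


@dataclass
class CellDensityField:
    """Standardized dFAD-weeks per 1-deg cell (distinct buoy-week pairs)."""

    grid: GridSpec
    values: np.ndarray    # (n_lat, n_lon) non-negative ints

    @property
    def total(self) -> int:
        return int(self.values.sum())

    def normalized(self) -> np.ndarray:
        """Optional max-normalized variant (max maps to 1)."""
        m = self.values.max()
        return self.values / m if m > 0 else self.values.astype(float)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"dfad_weeks": (("lat", "lon"), self.values)},
            coords={"lon": self.grid.lon_centers, "lat": self.grid.lat_centers})


def standardized_density(positions: pd.DataFrame, grid: GridSpec,
                         id_col: str = "buoy_id",
                         time_col: str = "timestamp") -> CellDensityField:
    """Count distinct (buoy, ISO week) pairs with >= 1 at-sea transmission
    per 1-deg cell.  A buoy crossing several cells in one week contributes
    to each; the same buoy counts again in later weeks."""
    vals = np.zeros((grid.n_lat, grid.n_lon), dtype=int)
    if len(positions) == 0:
        return CellDensityField(grid, vals)
    t = pd.to_datetime(positions[time_col])
    iso = t.dt.isocalendar()
    week_key = iso.year.astype(str) + "-W" + iso.week.astype(str)
    flat = grid.flat_cell_of(positions["lon"].to_numpy(float),
                             positions["lat"].to_numpy(float), strict=False)
    df = pd.DataFrame({"id": positions[id_col].to_numpy(),
                       "week": week_key.to_numpy(), "cell": flat})
    df = df[df["cell"] >= 0].drop_duplicates()
    counts = df.groupby("cell").size()
    vals.ravel()[counts.index.to_numpy()] = counts.to_numpy()
    return CellDensityField(grid, vals)


def nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference kernel standard deviation for one axis:
    1.06 * min(sd, IQR/1.34) * n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(np.mean(x)), 1.0) * 0.01   # degenerate cluster
    return 1.06 * spread * n ** (-0.2)


@dataclass
class DeploymentDensity:
    """Gaussian product-kernel density on a lon/lat lattice, normalized to
    integrate to 1 over the domain."""

    lon_nodes: np.ndarray
    lat_nodes: np.ndarray
    density: np.ndarray         # (n_lat_nodes, n_lon_nodes)
    bandwidth: tuple            # (sd_lon_deg, sd_lat_deg)

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.lon_nodes,
                                               axis=1), self.lat_nodes))

    def argmax(self) -> tuple:
        iy, ix = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.lon_nodes[ix]), float(self.lat_nodes[iy])

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset({"density": (("lat", "lon"), self.density)},
                        coords={"lon": self.lon_nodes, "lat": self.lat_nodes})
        ds.attrs["bandwidth_lon"] = self.bandwidth[0]
        ds.attrs["bandwidth_lat"] = self.bandwidth[1]
        return ds


def deployment_kde(lons, lats, grid: GridSpec, bandwidth: Optional[tuple] = None,
                   lattice_step: float = 0.1) -> DeploymentDensity:
    """2D product-kernel density of deployment positions on a regular lattice.

    The per-axis kernel sd defaults to the normal-reference rule.  The
    separable kernel makes the evaluation an outer product of the two
    one-dimensional kernel matrices.
    """
    lons = normalize_lon(np.asarray(lons, dtype=float))
    lons = np.where(lons < grid.lon_min, lons + 360.0, lons)
    lats = np.asarray(lats, dtype=float)
    n = len(lons)
    if n < 2:
        raise ValueError("need at least 2 deployments for a density estimate")
    if bandwidth is None:
        bandwidth = (nrd_bandwidth(lons), nrd_bandwidth(lats))
    hx, hy = bandwidth

    gx = np.arange(grid.lon_min + lattice_step / 2, grid.lon_max,
                   lattice_step)
    gy = np.arange(grid.lat_min + lattice_step / 2, grid.lat_max,
                   lattice_step)
    ax = np.exp(-0.5 * ((gx[:, None] - lons[None, :]) / hx) ** 2) / \
        (hx * np.sqrt(2 * np.pi))
    ay = np.exp(-0.5 * ((gy[:, None] - lats[None, :]) / hy) ** 2) / \
        (hy * np.sqrt(2 * np.pi))
    dens = (ay @ ax.T) / n
    integral = np.trapezoid(np.trapezoid(dens, gx, axis=1), gy)
    if integral > 0:
        dens = dens / integral
    return DeploymentDensity(gx, gy, dens, (hx, hy))


def cell_mean_density(kde: DeploymentDensity, grid: GridSpec) -> np.ndarray:
    """Mean lattice density inside each 1-deg cell, (n_lat, n_lon)."""
    lon_g, lat_g = np.meshgrid(kde.lon_nodes, kde.lat_nodes)
    flat = grid.flat_cell_of(lon_g.ravel(), lat_g.ravel(), strict=False)
    ok = flat >= 0
    sums = np.bincount(flat[ok], weights=kde.density.ravel()[ok],
                       minlength=grid.n_cells)
    counts = np.bincount(flat[ok], minlength=grid.n_cells)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return mean.reshape(grid.n_lat, grid.n_lon)


@dataclass
class Hotspots:
    """Hotspot cells and their connected components, labelled 1..k in
    decreasing total mass (0 = not a hotspot)."""

    grid: GridSpec
    cell_values: np.ndarray      # per-cell mean density
    threshold: float
    member: np.ndarray           # (n_lat, n_lon) bool
    component: np.ndarray        # (n_lat, n_lon) int labels

    @property
    def cells(self) -> set:
        rows, cols = np.nonzero(self.member)
        return set((rows * self.grid.n_lon + cols).tolist())

    @property
    def n_components(self) -> int:
        return int(self.component.max())

    def label_of_cell(self, flat: int) -> int:
        return int(self.component.ravel()[flat])


def hotspot_cells(kde: DeploymentDensity, grid: GridSpec,
                  percentile: float = 95.0) -> Hotspots:
    """Cells whose mean density strictly exceeds the given percentile of all
    1-deg cell values; 4-connected components ordered by total mass."""
    vals = cell_mean_density(kde, grid)
    thr = float(np.percentile(vals, percentile))
    member = vals > thr
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    raw_labels, n = ndimage.label(member, structure=structure)
    component = np.zeros_like(raw_labels)
    if n:
        masses = ndimage.sum_labels(vals, raw_labels, index=np.arange(1, n + 1))
        order = np.argsort(-masses)
        for rank, comp in enumerate(order, start=1):
            component[raw_labels == comp + 1] = rank
    return Hotspots(grid, vals, thr, member, component)
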