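"""Conductance rasters and least-cost-path distances between basin centroids.

Movement through the landscape is modelled on a conductance raster: each cell
holds a dimensionless ease-of-movement value, and the cost of stepping between
adjacent cells is the centre-to-centre distance divided by the mean conductance
of the two cells. Least-cost paths over the 8-neighbour cell graph give
between-basin cost distances, which an anchored linear transformation expresses
as kilometres. Two schemes are supported: river-following (water 50000, land
0.0001, sea 150) and elevation-weighted (five elevation bands from 1e6 below
100 m down to 0.001 at or above 2000 m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .rasters import AsciiGrid

EARTH_RADIUS_KM = 6371.0088

#: river-following scheme conductances
RIVER_FOLLOWING_VALUES = {"water": 50000.0, "land": 0.0001, "sea": 150.0}

#: elevation-weighted scheme: (lower bound m inclusive, upper bound m exclusive, conductance)
ELEVATION_BANDS = (
    (-math.inf, 100.0, 1_000_000.0),
    (100.0, 500.0, 100_000.0),
    (500.0, 1500.0, 1_000.0),
    (1500.0, 2000.0, 100.0),
    (2000.0, math.inf, 0.001),
)


@dataclass
class ConductanceRaster:
    grid: np.ndarray
    cell_size_km: float
    scheme: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.grid)) or np.any(self.grid <= 0):
            raise ValueError("conductance must be finite and strictly positive")


@dataclass
class CostDistanceResult:
    labels: list[str]
    cost: pd.DataFrame
    scheme: str
    km: pd.DataFrame | None = None


def build_conductance_raster(
    dem: AsciiGrid,
    river_raster: AsciiGrid,
    sea_mask: AsciiGrid,
    scheme: str,
    values: dict[str, float] | None = None,
    elevation_bands: tuple[tuple[float, float, float], ...] = ELEVATION_BANDS,
) -> ConductanceRaster:
    """Translate DEM + hydrology rasters into a conductance raster.

    ``river_following`` uses only the water/land/sea classification;
    ``elevation_weighted`` uses only the elevation bands (the two schemes are
    independent rasters, not overlays).
    """
    if not (dem.same_grid(river_raster) and dem.same_grid(sea_mask)):
        raise ValueError("DEM, river and sea rasters are not co-registered")
    bad = np.argwhere(~np.isfinite(dem.data) | (dem.data == dem.nodata_value))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"undefined elevation at cell ({r}, {c})")
    if scheme == "river_following":
        v = {**RIVER_FOLLOWING_VALUES, **(values or {})}
        grid = np.full(dem.shape, v["land"])
        grid[sea_mask.data > 0] = v["sea"]
        grid[river_raster.data > 0] = v["water"]
    elif scheme == "elevation_weighted":
        grid = np.empty(dem.shape)
        grid[:] = np.nan
        for lo, hi, cond in elevation_bands:
            sel = (dem.data >= lo) & (dem.data < hi)
            grid[sel] = cond
        if np.isnan(grid).any():
            raise ValueError("elevation bands do not cover the DEM range")
    else:
        raise ValueError(f"unknown conductance scheme {scheme!r}")
    return ConductanceRaster(grid=grid, cell_size_km=dem.cellsize, scheme=scheme)


def _cell_graph(raster: ConductanceRaster):
    """Sparse symmetric 8-neighbour graph; edge cost = distance / mean conductance."""
    rows, cols = raster.grid.shape
    c = raster.grid
    idx = np.arange(rows * cols).reshape(rows, cols)
    data, ii, jj = [], [], []
    for dr, dc, mult in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))):
        r0 = slice(0, rows - dr)
        r1 = slice(dr, rows)
        if dc >= 0:
            c0, c1 = slice(0, cols - dc), slice(dc, cols)
        else:
            c0, c1 = slice(-dc, cols), slice(0, cols + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        mean_c = (c[r0, c0].ravel() + c[r1, c1].ravel()) / 2.0
        d = mult * raster.cell_size_km / mean_c
        ii.append(a)
        jj.append(b)
        data.append(d)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    data = np.concatenate(data)
    n = rows * cols
    return coo_matrix((data, (ii, jj)), shape=(n, n)).tocsr()


def cost_distance(
    raster: ConductanceRaster,
    points: pd.DataFrame,
) -> CostDistanceResult:
    """All-pairs least-cost distances between basin centroid cells.

    ``points`` needs columns ``basin_id``, ``row``, ``col`` (cell indices on the
    raster grid). All conductances are positive, so every pair is reachable;
    numerically huge costs are reported as-is.
    """
    rows, cols = raster.grid.shape
    labels = points["basin_id"].tolist()
    rr = points["row"].to_numpy(dtype=int)
    cc = points["col"].to_numpy(dtype=int)
    if (rr < 0).any() or (rr >= rows).any() or (cc < 0).any() or (cc >= cols).any():
        raise ValueError("centroid falls outside the raster")
    nodes = rr * cols + cc
    graph = _cell_graph(raster)
    full = dijkstra(graph, directed=False, indices=nodes)
    cost = full[:, nodes]
    cost = (cost + cost.T) / 2.0
    np.fill_diagonal(cost, 0.0)
    return CostDistanceResult(
        labels=labels,
        cost=pd.DataFrame(cost, index=labels, columns=labels),
        scheme=raster.scheme,
    )


def cost_to_km(
    result: CostDistanceResult,
    reference_conductance: float = RIVER_FOLLOWING_VALUES["water"],
) -> CostDistanceResult:
    """Express cost distances in kilometres, anchored so a path running entirely
    through reference-conductance cells (water in the river-following scheme)
    reads as its along-path geographic length. Monotone and order-preserving."""
    return replace(result, km=result.cost * reference_conductance)


def euclidean_km(points: pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) distances in km between centroids given as
    decimal-degree ``lon``/``lat`` columns indexed or labelled by ``basin_id``."""
    labels = points["basin_id"].tolist() if "basin_id" in points else list(points.index)
    lon = np.radians(points["lon"].to_numpy(dtype=float))
    lat = np.radians(points["lat"].to_numpy(dtype=float))
    if (np.abs(points["lat"].to_numpy()) > 90).any() or (np.abs(points["lon"].to_numpy()) > 360).any():
        raise ValueError("coordinates out of range")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)
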