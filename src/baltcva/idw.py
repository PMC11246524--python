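"""Species distribution gridding from haul-level survey CPUE.

Haul records (survey, year, lat, lon, species, CPUE) are interpolated
onto the assessment's 0.05 deg x 0.05 deg grid by inverse distance
weighting over the k nearest hauls, one surface per year; the final
distribution map is the per-cell median over years.  Distances are
degree-space with a cos(latitude) correction on longitude, matching the
anisotropic ~3 x 6 km cells of the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

SURVEYS = ("BITS", "BIAS", "BASS")

HAUL_COLUMNS = ("survey", "year", "lat", "lon", "species", "cpue")


@dataclass(frozen=True)
class GridSpec:
    """Regular cell-center-registered lat/lon grid."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.05

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        half = self.resolution / 2
        lats = np.arange(self.lat_min + half, self.lat_max, self.resolution)
        lons = np.arange(self.lon_min + half, self.lon_max, self.resolution)
        return lats, lons


def validate_hauls(hauls: pd.DataFrame, grid: GridSpec | None = None) -> pd.DataFrame:
    missing = set(HAUL_COLUMNS) - set(hauls.columns)
    if missing:
        raise ValueError(f"haul table is missing columns {sorted(missing)}")
    if (hauls["cpue"] < 0).any():
        bad = hauls.index[hauls["cpue"] < 0].tolist()[:5]
        raise ValueError(f"negative CPUE in haul rows {bad}")
    unknown = set(hauls["survey"]) - set(SURVEYS)
    if unknown:
        raise ValueError(f"unknown survey codes {sorted(unknown)}; expected {SURVEYS}")
    if grid is not None:
        inside = (
            hauls["lat"].between(grid.lat_min, grid.lat_max)
            & hauls["lon"].between(grid.lon_min, grid.lon_max)
        )
        if not inside.all():
            bad = hauls.index[~inside].tolist()[:5]
            raise ValueError(f"haul coordinates outside the grid bounding box, rows {bad}")
    return hauls


def _scaled_coords(lat: np.ndarray, lon: np.ndarray, ref_lat: float) -> np.ndarray:
    # cos(latitude) shrinks longitudinal degrees to match latitudinal ones
    scale = np.cos(np.deg2rad(ref_lat))
    return np.column_stack([lat, lon * scale])


def idw_grid(hauls: pd.DataFrame, species: str, grid: GridSpec,
             power: float = 2.0, k: int = 12,
             distance_floor: float = 1e-6) -> xr.DataArray:
    """Yearly IDW surfaces of CPUE for one species.

    Each cell value is sum(w_i * cpue_i) / sum(w_i) with w_i = d_i^-power
    over the k nearest hauls of that year; a haul closer to the cell
    center than ``distance_floor`` (degrees) dominates exactly, making
    the interpolation exact at haul locations.  Returns a DataArray with
    dims (year, lat, lon); years with no hauls are absent.
    """
    validate_hauls(hauls)
    sub = hauls[hauls["species"] == species]
    lats, lons = grid.centers()
    if sub.empty:
        log.warning("no hauls for species %r; returning empty map", species)
        return xr.DataArray(
            np.empty((0, lats.size, lons.size)),
            coords={"year": np.array([], dtype=int), "lat": lats, "lon": lons},
            dims=("year", "lat", "lon"),
        )
    ref_lat = 0.5 * (grid.lat_min + grid.lat_max)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    cell_xy = _scaled_coords(glat.ravel(), glon.ravel(), ref_lat)

    years = sorted(sub["year"].unique())
    surfaces = np.empty((len(years), lats.size, lons.size))
    for yi, year in enumerate(years):
        pts = sub[sub["year"] == year]
        haul_xy = _scaled_coords(pts["lat"].to_numpy(), pts["lon"].to_numpy(), ref_lat)
        values = pts["cpue"].to_numpy(dtype=float)
        kk = min(k, len(pts))
        tree = cKDTree(haul_xy)
        dist, idx = tree.query(cell_xy, k=kk)
        if kk == 1:
            dist, idx = dist[:, None], idx[:, None]
        near = dist < distance_floor
        with np.errstate(divide="ignore"):
            w = dist ** (-power)
        # a coincident haul takes the cell exactly
        w[near.any(axis=1)[:, None] & ~near] = 0.0
        w[near] = 1.0
        est = (w * values[idx]).sum(axis=1) / w.sum(axis=1)
        surfaces[yi] = est.reshape(lats.size, lons.size)
    return xr.DataArray(
        surfaces,
        coords={"year": np.asarray(years, dtype=int), "lat": lats, "lon": lons},
        dims=("year", "lat", "lon"),
    )


def median_over_years(yearly: xr.DataArray) -> xr.DataArray:
    """Per-cell median of annual surfaces, ignoring missing years."""
    if yearly.sizes.get("year", 0) == 0:
        raise ValueError("no yearly surfaces to take a median over")
    return yearly.median(dim="year", skipna=True)
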