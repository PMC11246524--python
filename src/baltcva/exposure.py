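"""Climate-exposure maps from gridded temperature decades.

Exposure to warming is measured per grid cell as the absolute Z-score

    |Z| = |(Xf_mean - Xr_mean) / Xr_sd|

contrasting a future decade against the 2010-2019 reference decade, then
binned into four exposure categories.  The sign of the change is
discarded: only the magnitude of departure from reference variability
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

EXPOSURE_BINS = ("low", "moderate", "high", "very_high")
DEPTH_LAYERS = ("surface", "bottom")
SEASONS = ("annual", "Q1", "Q2", "Q3", "Q4")

#: the study's three scenario contrasts against the 2010-2019 reference
SCENARIOS = ("RCP45_MOC", "RCP45_EOC", "RCP85_EOC")
REFERENCE_PERIOD = "2010-2019"

GRID_RESOLUTION = 0.05  # degrees, cell-center registered


@dataclass
class TemperatureCube:
    """Per-cell, per-year mean temperatures for one decade.

    ``data`` is an xarray DataArray with dims (year, lat, lon) in degrees
    Celsius; land/invalid cells are NaN across all years.  A decade spans
    exactly 10 consecutive calendar years unless ``strict=False``.
    """

    data: xr.DataArray
    decade: str = ""
    depth_layer: str = "bottom"
    season: str = "annual"
    strict: bool = True

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != ("year", "lat", "lon"):
            raise ValueError(f"cube dims {self.data.dims} != ('year', 'lat', 'lon')")
        if self.depth_layer not in DEPTH_LAYERS:
            raise ValueError(f"depth_layer {self.depth_layer!r} not in {DEPTH_LAYERS}")
        if self.season not in SEASONS:
            raise ValueError(f"season {self.season!r} not in {SEASONS}")
        years = np.asarray(self.data["year"])
        if years.size < 2:
            raise ValueError("a decade needs at least 2 years")
        if not np.all(np.diff(years) == 1):
            raise ValueError(f"years {years} are not consecutive")
        if self.strict and years.size != 10:
            raise ValueError(f"decade spans {years.size} years, expected exactly 10")

    @property
    def mask(self) -> xr.DataArray:
        """True where a cell is invalid (NaN in every year)."""
        return self.data.isnull().all(dim="year")

    def same_grid(self, other: "TemperatureCube") -> bool:
        return (
            self.data["lat"].equals(other.data["lat"])
            and self.data["lon"].equals(other.data["lon"])
        )


def decadal_stats(cube: TemperatureCube, ddof: int = 1) -> tuple[xr.DataArray, xr.DataArray]:
    """Per-cell mean and standard deviation over the decade's years.

    The SD divisor defaults to n-1 (sample SD).  Fully masked cells stay
    NaN in both outputs.
    """
    mean = cube.data.mean(dim="year", skipna=False)
    sd = cube.data.std(dim="year", ddof=ddof, skipna=False)
    return mean, sd


def bin_z(z):
    """Exposure bin(s) for non-negative |Z| values.

    low: |Z| <= 0.5; moderate: 0.5 < |Z| <= 1.5; high: 1.5 < |Z| <= 2.0;
    very_high: |Z| > 2.0 (including infinite |Z|).  NaN stays NaN.
    """
    arr = np.asarray(z, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("negative |Z| value passed to bin_z")
    out = np.full(arr.shape, None, dtype=object)
    out[arr <= 0.5] = "low"
    out[(arr > 0.5) & (arr <= 1.5)] = "moderate"
    out[(arr > 1.5) & (arr <= 2.0)] = "high"
    out[arr > 2.0] = "very_high"
    if np.isscalar(z) or arr.shape == ():
        return out.item()
    return out


@dataclass
class ZScoreMap:
    """Per-cell |Z| and exposure bin for one scenario contrast."""

    z: xr.DataArray
    bins: xr.DataArray
    scenario: str = ""
    reference_period: str = REFERENCE_PERIOD
    n_infinite: int = 0

    def bin_fractions(self) -> pd.Series:
        """Fraction of unmasked cells in each exposure bin."""
        flat = self.bins.values.ravel()
        valid = flat[pd.notna(flat)]
        counts = pd.Series(valid).value_counts()
        return pd.Series({b: counts.get(b, 0) / len(valid) for b in EXPOSURE_BINS})


def z_score_map(reference: TemperatureCube, future: TemperatureCube,
                scenario: str = "") -> ZScoreMap:
    """Absolute Z-score of a future decade against the reference decade.

    Cells where the reference SD is zero get |Z| = 0 if the means agree
    and +inf (binned very_high, counted in ``n_infinite``) otherwise: a
    finite change against zero reference variability is maximal surprise.
    """
    if not reference.same_grid(future):
        raise ValueError("reference and future cubes are on different grids")
    for attr in ("depth_layer", "season"):
        if getattr(reference, attr) != getattr(future, attr):
            raise ValueError(
                f"{attr} mismatch: {getattr(reference, attr)!r} vs {getattr(future, attr)!r}"
            )
    ref_mean, ref_sd = decadal_stats(reference)
    fut_mean, _ = decadal_stats(future)
    diff = np.abs(fut_mean - ref_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / ref_sd
    zero_sd = (ref_sd == 0)
    z = xr.where(zero_sd & (diff == 0), 0.0, z)
    z = xr.where(zero_sd & (diff > 0), np.inf, z)
    z = z.where(~reference.mask & ~future.mask)
    n_infinite = int(np.isinf(z.values).sum())
    bins = xr.DataArray(bin_z(z.values), coords=z.coords, dims=z.dims)
    return ZScoreMap(z=z, bins=bins, scenario=scenario, n_infinite=n_infinite)


def overlap_summary(dist: xr.DataArray, zmap: ZScoreMap) -> pd.Series:
    """CPUE-weighted fraction of a species distribution in each exposure bin.

    For each bin, the summed CPUE over that bin's cells divided by the
    total CPUE over all unmasked cells; fractions sum to 1.
    """
    if not (dist["lat"].equals(zmap.z["lat"]) and dist["lon"].equals(zmap.z["lon"])):
        raise ValueError("distribution map and Z-score map are on different grids")
    cpue = dist.values.astype(float)
    bins = zmap.bins.values
    valid = pd.notna(bins) & ~np.isnan(cpue)
    total = cpue[valid].sum()
    if total <= 0:
        raise ValueError("zero total CPUE mass; overlap fractions undefined")
    fractions = {
        b: float(cpue[valid & (bins == b)].sum() / total) for b in EXPOSURE_BINS
    }
    return pd.Series(fractions)
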