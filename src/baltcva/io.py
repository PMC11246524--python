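"""Readers and writers for the declared exchange formats.

Tally tables, data-quality tables, haul tables and score outputs travel
as long-format UTF-8 CSV; temperature cubes and gridded maps travel as
CF-style NetCDF (lat/lon/year) with a plain long-CSV fallback.  Reads
validate against the schema and name the offending record on failure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .exposure import TemperatureCube, ZScoreMap
from .panel import ExpertPanel
from .scoring import AttributeScoreMatrix
from .tallies import DIRECTION_BINS, SENSITIVITY_BINS

TALLY_COLUMNS = ("expert_id", "species", "kind", "attribute_or_factor", "bin", "count")
KINDS = ("sensitivity", "exposure", "direction")


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def _check_columns(df: pd.DataFrame, required, what: str, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{what} {path}: missing columns {sorted(missing)}")


def read_panels(path) -> dict[str, ExpertPanel]:
    """Read a long-format tally CSV into panels keyed by assessment kind.

    Returns ``{"sensitivity": panel, "exposure": panel}`` (either may be
    absent); direction tallies attach to the sensitivity panel, which is
    created on demand.  Line numbers in errors refer to the CSV file
    (header = line 1).
    """
    df = pd.read_csv(path)
    _check_columns(df, TALLY_COLUMNS, "tally CSV", path)
    for i, row in df.iterrows():
        line = i + 2
        if row["kind"] not in KINDS:
            raise SchemaError(f"{path} line {line}: unknown kind {row['kind']!r}")
        bins = DIRECTION_BINS if row["kind"] == "direction" else SENSITIVITY_BINS
        if row["bin"] not in bins:
            raise SchemaError(
                f"{path} line {line}: unknown bin label {row['bin']!r} for kind {row['kind']!r}"
            )
        if float(row["count"]) != int(row["count"]) or int(row["count"]) < 0:
            raise SchemaError(f"{path} line {line}: invalid tally count {row['count']!r}")

    panels: dict[str, ExpertPanel] = {}

    def panel_for(kind: str) -> ExpertPanel:
        key = "sensitivity" if kind == "direction" else kind
        return panels.setdefault(key, ExpertPanel())

    group_cols = ["expert_id", "species", "kind", "attribute_or_factor"]
    for (expert, species, kind, attr), grp in df.groupby(group_cols, sort=True, dropna=False):
        bins = DIRECTION_BINS if kind == "direction" else SENSITIVITY_BINS
        counts = grp.set_index("bin")["count"]
        if counts.index.duplicated().any():
            raise SchemaError(
                f"{path}: duplicate bin rows for ({expert}, {species}, {attr})"
            )
        vec = tuple(int(counts.get(b, 0)) for b in bins)
        if kind == "direction":
            panel_for(kind).add_direction(str(expert), str(species), vec)
        else:
            panel_for(kind).add_tally(str(expert), str(species), str(attr), vec)
    return panels


def write_panels(panels: dict[str, ExpertPanel], path) -> None:
    """Write panels back to the long tally CSV schema (round-trip safe)."""
    rows = []
    for kind in ("sensitivity", "exposure"):
        panel = panels.get(kind)
        if panel is None:
            continue
        for (expert, species, attr), tally in sorted(panel.entries.items()):
            for b, c in zip(SENSITIVITY_BINS, tally.counts):
                rows.append((expert, species, kind, attr, b, c))
        if kind == "sensitivity":
            for (expert, species), tally in sorted(panel.directional.items()):
                for b, c in zip(DIRECTION_BINS, tally.counts):
                    rows.append((expert, species, "direction", "overall", b, c))
    pd.DataFrame(rows, columns=list(TALLY_COLUMNS)).to_csv(path, index=False)


def read_quality(path, panel: ExpertPanel) -> ExpertPanel:
    """Attach a data-quality CSV (expert_id, species, attribute_or_factor, quality)."""
    df = pd.read_csv(path)
    _check_columns(df, ("expert_id", "species", "attribute_or_factor", "quality"), "quality CSV", path)
    for i, row in df.iterrows():
        q = row["quality"]
        if q not in (0, 1, 2, 3):
            raise SchemaError(f"{path} line {i + 2}: quality {q!r} outside {{0,1,2,3}}")
        panel.add_quality(str(row["expert_id"]), str(row["species"]),
                          str(row["attribute_or_factor"]), int(q))
    return panel


def write_quality(panel: ExpertPanel, path) -> None:
    rows = [(e, s, a, q) for (e, s, a), q in sorted(panel.data_quality.items())]
    pd.DataFrame(rows, columns=["expert_id", "species", "attribute_or_factor", "quality"]
                 ).to_csv(path, index=False)


def write_scores(matrix: AttributeScoreMatrix, tidy_path, wide_path=None) -> None:
    """Score outputs: tidy (species, attribute, score, n_tallies, mean_quality)
    and optionally the wide species x attribute matrix."""
    tidy = (
        matrix.scores.stack(future_stack=True).rename("score").reset_index()
        .rename(columns={"level_0": "species", "level_1": "attribute"})
    )
    tidy["n_tallies"] = [
        matrix.n_tallies.loc[s, a] for s, a in zip(tidy["species"], tidy["attribute"])
    ]
    tidy["mean_quality"] = [
        matrix.quality.loc[s, a] for s, a in zip(tidy["species"], tidy["attribute"])
    ]
    tidy.to_csv(tidy_path, index=False)
    if wide_path is not None:
        matrix.scores.rename_axis("species").to_csv(wide_path)


def read_cube(path, decade: str = "", depth_layer: str = "bottom",
              season: str = "annual", strict: bool = True) -> TemperatureCube:
    """Read a temperature cube from NetCDF (.nc) or long CSV.

    CSV schema: lat, lon, year, value; masked cells as NaN or absent rows.
    """
    path = Path(path)
    if path.suffix == ".nc":
        ds = xr.open_dataset(path, engine="scipy")
        da = ds["temperature"].transpose("year", "lat", "lon").load()
        ds.close()
        meta = ds.attrs
        return TemperatureCube(
            data=da,
            decade=meta.get("decade", decade),
            depth_layer=meta.get("depth_layer", depth_layer),
            season=meta.get("season", season),
            strict=strict,
        )
    df = pd.read_csv(path)
    _check_columns(df, ("lat", "lon", "year", "value"), "cube CSV", path)
    if df[["lat", "lon", "year"]].isna().any().any():
        bad = df.index[df[["lat", "lon", "year"]].isna().any(axis=1)][0]
        raise SchemaError(f"{path} line {bad + 2}: malformed coordinates")
    da = (
        df.set_index(["year", "lat", "lon"])["value"]
        .to_xarray().transpose("year", "lat", "lon").rename("temperature")
    )
    return TemperatureCube(data=da, decade=decade, depth_layer=depth_layer,
                           season=season, strict=strict)


def write_cube(cube: TemperatureCube, path) -> None:
    path = Path(path)
    if path.suffix == ".nc":
        ds = cube.data.rename("temperature").to_dataset()
        ds.attrs.update(decade=cube.decade, depth_layer=cube.depth_layer, season=cube.season)
        ds.to_netcdf(path, engine="scipy")
        return
    df = cube.data.rename("value").to_dataframe().reset_index()
    df[["lat", "lon", "year", "value"]].to_csv(path, index=False)


def write_map(da_or_zmap, path) -> None:
    """Write a gridded map (DistributionMap DataArray or ZScoreMap).

    Long CSV (lat, lon, value[, bin]) or NetCDF by extension.
    """
    path = Path(path)
    if isinstance(da_or_zmap, ZScoreMap):
        zmap = da_or_zmap
        if path.suffix == ".nc":
            codes = xr.DataArray(
                np.where(pd.isna(zmap.bins.values), "", zmap.bins.values.astype(str)),
                coords=zmap.z.coords, dims=zmap.z.dims)
            ds = xr.Dataset({"z": zmap.z, "bin": codes})
            ds.attrs.update(scenario=zmap.scenario, reference_period=zmap.reference_period)
            ds.to_netcdf(path, engine="scipy")
        else:
            df = zmap.z.rename("z").to_dataframe().reset_index()
            df["bin"] = zmap.bins.values.ravel()
            df.to_csv(path, index=False)
        return
    da = da_or_zmap
    if path.suffix == ".nc":
        da.rename("value").to_dataset().to_netcdf(path, engine="scipy")
    else:
        da.rename("value").to_dataframe().reset_index().to_csv(path, index=False)


def read_hauls(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ("survey", "year", "lat", "lon", "species", "cpue"), "haul CSV", path)
    return df
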