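"""Species roster and sensitivity-attribute definitions.

The package ships transcriptions of the assessment's species list
(22 Western Baltic fish species with their ecotype) and the 12
trait-based sensitivity attributes with their low/high scoring anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

ECOTYPES = ("marine", "anadromous", "catadromous", "freshwater-brackish")

#: canonical short keys of the 12 sensitivity attributes
ATTRIBUTE_KEYS = (
    "habitat", "prey", "mobility", "dispersal", "ELH", "complexity",
    "spawning", "temperature", "salinity", "acidification", "growth", "other",
)


@dataclass(frozen=True)
class SpeciesRecord:
    scientific_name: str
    common_name: str
    ecotype: str

    def __post_init__(self) -> None:
        if self.ecotype not in ECOTYPES:
            raise ValueError(
                f"unknown ecotype {self.ecotype!r} for {self.common_name};"
                f" expected one of {ECOTYPES}"
            )


@dataclass(frozen=True)
class AttributeDef:
    key: str
    full_name: str
    low_anchor: str
    high_anchor: str


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("baltcva.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_species_roster(path=None) -> pd.DataFrame:
    """Load the species roster (packaged transcription by default).

    Returns a DataFrame with columns scientific_name, common_name, label,
    ecotype.  Common names must be unique and ecotypes canonical.
    """
    df = pd.read_csv(path) if path is not None else _packaged("species_roster.csv")
    required = {"scientific_name", "common_name", "ecotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"roster is missing columns {sorted(missing)}")
    if df["common_name"].duplicated().any():
        dupes = df.loc[df["common_name"].duplicated(), "common_name"].tolist()
        raise ValueError(f"duplicate common names in roster: {dupes}")
    bad = set(df["ecotype"]) - set(ECOTYPES)
    if bad:
        raise ValueError(f"unknown ecotypes in roster: {sorted(bad)}")
    return df


def load_attribute_definitions(path=None) -> pd.DataFrame:
    """Load the 12 sensitivity-attribute definitions.

    The key set must equal the canonical attribute set; order follows the
    file, which mirrors the assessment's attribute table.
    """
    df = pd.read_csv(path) if path is not None else _packaged("sensitivity_attributes.csv")
    required = {"key", "full_name", "low_anchor", "high_anchor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"attribute table is missing columns {sorted(missing)}")
    keys = list(df["key"])
    if sorted(keys) != sorted(ATTRIBUTE_KEYS):
        raise ValueError(
            f"attribute keys {keys} do not match the canonical set {list(ATTRIBUTE_KEYS)}"
        )
    return df


def species_records(df: pd.DataFrame | None = None) -> list[SpeciesRecord]:
    df = load_species_roster() if df is None else df
    return [
        SpeciesRecord(r.scientific_name, r.common_name, r.ecotype)
        for r in df.itertuples()
    ]


def attribute_defs(df: pd.DataFrame | None = None) -> list[AttributeDef]:
    df = load_attribute_definitions() if df is None else df
    return [
        AttributeDef(r.key, r.full_name, r.low_anchor, r.high_anchor)
        for r in df.itertuples()
    ]
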