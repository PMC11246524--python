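"""The expert panel: every tally and data-quality score of one elicitation.

An ``ExpertPanel`` holds the 4-bin tallies of one assessment (sensitivity
or exposure), the 3-bin directional tallies collected alongside the
sensitivity assessment, and the 0-3 data-quality ratings.  Exposure
panels carry a single factor (``"temperature"``) where sensitivity panels
carry the 12 attributes; the machinery is identical.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .tallies import (
    DIRECTION_BUDGET,
    SENSITIVITY_BUDGET,
    DirectionalTally,
    SensitivityTally,
    TallyError,
    validate_tally,
)

QUALITY_LEVELS = (0, 1, 2, 3)  # 3 = adequate data ... 0 = no data available


@dataclass
class ExpertPanel:
    """Tallies and quality scores keyed by (expert, species, attribute)."""

    entries: dict[tuple[str, str, str], SensitivityTally] = field(default_factory=dict)
    directional: dict[tuple[str, str], DirectionalTally] = field(default_factory=dict)
    data_quality: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def add_tally(self, expert: str, species: str, attribute: str, counts) -> None:
        tally = counts if isinstance(counts, SensitivityTally) else SensitivityTally(tuple(counts))
        validate_tally(tally, SENSITIVITY_BUDGET, context=f"({expert}, {species}, {attribute})")
        self.entries[(expert, species, attribute)] = tally

    def add_direction(self, expert: str, species: str, counts) -> None:
        tally = counts if isinstance(counts, DirectionalTally) else DirectionalTally(tuple(counts))
        validate_tally(tally, DIRECTION_BUDGET, context=f"({expert}, {species})")
        self.directional[(expert, species)] = tally

    def add_quality(self, expert: str, species: str, attribute: str, quality: int) -> None:
        if quality not in QUALITY_LEVELS:
            raise ValueError(
                f"data quality {quality!r} outside {{0,1,2,3}} in ({expert}, {species}, {attribute})"
            )
        self.data_quality[(expert, species, attribute)] = int(quality)

    # -- views ---------------------------------------------------------------

    @property
    def experts(self) -> list[str]:
        names = {k[0] for k in self.entries} | {k[0] for k in self.directional}
        return sorted(names)

    @property
    def species(self) -> list[str]:
        names = {k[1] for k in self.entries} | {k[1] for k in self.directional}
        return sorted(names)

    @property
    def attributes(self) -> list[str]:
        return sorted({k[2] for k in self.entries})

    def cell_tallies(self, species: str, attribute: str) -> list[SensitivityTally]:
        """All expert tallies for one (species, attribute) cell, expert-ordered."""
        keys = sorted(k for k in self.entries if k[1] == species and k[2] == attribute)
        return [self.entries[k] for k in keys]

    def species_directions(self, species: str) -> list[DirectionalTally]:
        keys = sorted(k for k in self.directional if k[1] == species)
        return [self.directional[k] for k in keys]

    def cell_quality(self, species: str, attribute: str) -> list[int]:
        keys = sorted(k for k in self.data_quality if k[1] == species and k[2] == attribute)
        return [self.data_quality[k] for k in keys]

    def cells(self) -> dict[tuple[str, str], list[SensitivityTally]]:
        """Mapping (species, attribute) -> expert tallies, in deterministic order."""
        grouped: dict[tuple[str, str], list] = defaultdict(list)
        for key in sorted(self.entries):
            expert, species, attribute = key
            grouped[(species, attribute)].append(self.entries[key])
        return dict(grouped)

    def validate(self) -> "ExpertPanel":
        """Re-check every stored tally and quality value; return self."""
        for (expert, species, attribute), tally in self.entries.items():
            validate_tally(tally, SENSITIVITY_BUDGET, context=f"({expert}, {species}, {attribute})")
        for (expert, species), tally in self.directional.items():
            validate_tally(tally, DIRECTION_BUDGET, context=f"({expert}, {species})")
        for (expert, species, attribute), q in self.data_quality.items():
            if q not in QUALITY_LEVELS:
                raise ValueError(
                    f"data quality {q!r} outside {{0,1,2,3}} in ({expert}, {species}, {attribute})"
                )
        if not self.entries:
            raise TallyError("panel holds no tally entries")
        return self
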