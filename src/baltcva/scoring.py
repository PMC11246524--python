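"""Scoring rules of the vulnerability assessment.

The elicitation is summarized per species x attribute cell by the
tally-weighted mean score

    X = (L*1 + M*2 + H*3 + VH*4) / (L + M + H + VH)

on the ordinal 1-4 scale, pooled over all experts.  Species-level
sensitivity is either the numeric average of the 12 attribute scores or
a count-based logic rule over attribute means; exposure and vulnerability
are categorized on printed numeric breakpoints; directional effects are
a signed weighted mean on [-1, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ExpertPanel
from .tallies import pool_tallies

log = logging.getLogger(__name__)

CATEGORIES = ("L", "M", "H", "VH")
CATEGORY_RANK = {"L": 1, "M": 2, "H": 3, "VH": 4}
DIRECTION_CLASSES = ("negative", "neutral", "positive")

#: half-width of the neutral band for directional effects (as printed)
NEUTRAL_BAND = 0.333


@dataclass(frozen=True)
class CategoryScale:
    """Numeric category breakpoints on the 1-4 score scale.

    The printed intervals (VH >= 3.25, H = 2.50-3.25, M = 1.75-2.49,
    L = 1.00-1.74) overlap at 3.25 and leave the gaps 1.74-1.75 and
    2.49-2.50 unassigned; the scale resolves them as lower-closed
    half-open intervals with VH claiming 3.25, so every score in [1, 4]
    maps to exactly one category and each printed inequality holds.
    """

    lower_bounds: dict[str, float] = field(
        default_factory=lambda: {"L": 1.0, "M": 1.75, "H": 2.5, "VH": 3.25}
    )

    def categorize(self, score: float) -> str:
        if not (1.0 <= score <= 4.0) or math.isnan(score):
            raise ValueError(f"score {score} outside the [1, 4] scale")
        for cat in ("VH", "H", "M"):
            if score >= self.lower_bounds[cat]:
                return cat
        return "L"


DEFAULT_SCALE = CategoryScale()


def weighted_mean_score(pooled) -> float:
    """Tally-weighted mean score of a pooled 4-bin tally, in [1, 4]."""
    counts = np.asarray(getattr(pooled, "counts", pooled), dtype=float)
    if counts.shape != (4,):
        raise ValueError(f"expected 4 bin counts, got shape {counts.shape}")
    total = counts.sum()
    if total <= 0:
        raise ValueError("no tallies to score (zero total count)")
    ranks = np.arange(1, 5, dtype=float)
    return float(counts @ ranks / total)


def directional_effect(pooled) -> float:
    """Signed weighted mean of a pooled (Neg, Neu, Pos) tally, in [-1, 1]."""
    counts = np.asarray(getattr(pooled, "counts", pooled), dtype=float)
    if counts.shape != (3,):
        raise ValueError(f"expected 3 bin counts, got shape {counts.shape}")
    total = counts.sum()
    if total <= 0:
        raise ValueError("no tallies to score (zero total count)")
    weights = np.array([-1.0, 0.0, 1.0])
    return float(counts @ weights / total)


def classify_direction(de: float) -> str:
    """Map a directional effect to negative / neutral / positive.

    The neutral band is the closed interval [-0.333, 0.333]; the strict
    inequalities apply outside it.
    """
    if not (-1.0 <= de <= 1.0):
        raise ValueError(f"directional effect {de} outside [-1, 1]")
    if de < -NEUTRAL_BAND:
        return "negative"
    if de > NEUTRAL_BAND:
        return "positive"
    return "neutral"


def numeric_category(score: float, scale: CategoryScale = DEFAULT_SCALE) -> str:
    """Categorize a numeric 1-4 score on the printed breakpoints."""
    return scale.categorize(score)


def logic_rule_category(row) -> str:
    """Count-based species categorization over attribute mean scores.

    VH when >= 3 attributes score >= 3.5; else H when >= 2 score >= 3.0;
    else M when >= 2 score >= 2.5; else L.  Precedence VH > H > M > L:
    the first satisfied rule wins.
    """
    scores = np.asarray(pd.Series(row).dropna(), dtype=float)
    if scores.size == 0:
        raise ValueError("no attribute scores to categorize")
    if (scores >= 3.5).sum() >= 3:
        return "VH"
    if (scores >= 3.0).sum() >= 2:
        return "H"
    if (scores >= 2.5).sum() >= 2:
        return "M"
    return "L"


def numeric_sensitivity(row, weights=None, max_missing: int = 2) -> float:
    """Species sensitivity as the (un)weighted mean of attribute scores.

    With no published attribute weights the default is the plain
    arithmetic mean over the 12 attributes.  Up to ``max_missing``
    missing attributes are tolerated (mean over the present ones, with a
    logged warning); more are an error.
    """
    series = pd.Series(row, dtype=float)
    missing = series.isna().sum()
    if missing > max_missing:
        raise ValueError(
            f"{missing} of {series.size} attribute scores missing; at most {max_missing} allowed"
        )
    if missing:
        log.warning("averaging over %d of %d attributes (%d missing)",
                    series.size - missing, series.size, missing)
    present = series.dropna()
    if weights is None:
        return float(present.mean())
    w = pd.Series(weights, dtype=float).reindex(present.index)
    if w.isna().any():
        raise ValueError("weight vector does not cover all present attributes")
    return float((present * w).sum() / w.sum())


def vulnerability_score(sensitivity: float, exposure: float,
                        mode: str = "geometric_mean") -> float:
    """Combine sensitivity and exposure into a vulnerability score.

    ``geometric_mean`` (default) returns sqrt(s*e) on the 1-4 scale and
    is the only mode compatible with :func:`numeric_category`;
    ``product`` returns the raw product s*e on [1, 16].
    """
    for name, v in (("sensitivity", sensitivity), ("exposure", exposure)):
        if not (1.0 <= v <= 4.0):
            raise ValueError(f"{name} score {v} outside [1, 4]")
    if mode == "product":
        return float(sensitivity * exposure)
    if mode == "geometric_mean":
        return float(math.sqrt(sensitivity * exposure))
    raise ValueError(f"unknown vulnerability mode {mode!r}")


@dataclass
class AttributeScoreMatrix:
    """Species x attribute weighted-mean scores with companions.

    ``scores`` holds the pooled weighted-mean score per cell (NaN where a
    cell has no expert entries — missing cells are reported, never
    imputed); ``n_tallies`` the pooled tally count; ``quality`` the mean
    data-quality per cell.
    """

    scores: pd.DataFrame
    n_tallies: pd.DataFrame
    quality: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.scores.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.scores.columns)

    def missing_cells(self) -> list[tuple[str, str]]:
        mask = self.scores.isna()
        return [(s, a) for s in mask.index for a in mask.columns if mask.loc[s, a]]


def attribute_score_matrix(panel: ExpertPanel, species=None, attributes=None) -> AttributeScoreMatrix:
    """Pool each cell's tallies across experts and apply the weighted mean.

    Rows/columns default to the species/attributes present in the panel;
    passing explicit lists surfaces fully missing rows as NaN rather than
    dropping them silently.
    """
    panel.validate()
    species = list(species) if species is not None else panel.species
    attributes = list(attributes) if attributes is not None else panel.attributes
    scores = pd.DataFrame(np.nan, index=species, columns=attributes, dtype=float)
    n_tallies = pd.DataFrame(0, index=species, columns=attributes, dtype=int)
    quality = pd.DataFrame(np.nan, index=species, columns=attributes, dtype=float)
    for sp in species:
        for attr in attributes:
            tallies = panel.cell_tallies(sp, attr)
            if tallies:
                pooled = pool_tallies(tallies)
                scores.loc[sp, attr] = weighted_mean_score(pooled)
                n_tallies.loc[sp, attr] = int(pooled.sum())
            else:
                log.warning("no expert tallies for cell (%s, %s); flagged missing", sp, attr)
            qualities = panel.cell_quality(sp, attr)
            if qualities:
                quality.loc[sp, attr] = float(np.mean(qualities))
    return AttributeScoreMatrix(scores=scores, n_tallies=n_tallies, quality=quality)


def directional_effects(panel: ExpertPanel) -> pd.DataFrame:
    """Pooled directional effect and class per species."""
    rows = []
    for sp in sorted({k[1] for k in panel.directional}):
        pooled = pool_tallies(panel.species_directions(sp))
        de = directional_effect(pooled)
        rows.append({"species": sp, "directional_effect": de,
                     "direction_class": classify_direction(de)})
    return pd.DataFrame(rows).set_index("species")


def data_quality_summary(panel: ExpertPanel):
    """Mean data quality per (species, attribute) cell and per species.

    The species-level mean averages the attribute-level means, so every
    attribute counts equally regardless of how many experts rated it.
    """
    for key, q in panel.data_quality.items():
        if q not in (0, 1, 2, 3):
            raise ValueError(f"data quality {q!r} outside {{0,1,2,3}} in {key}")
    cells: dict[tuple[str, str], list[int]] = {}
    for (expert, sp, attr), q in panel.data_quality.items():
        cells.setdefault((sp, attr), []).append(q)
    cell_means = pd.Series({k: float(np.mean(v)) for k, v in cells.items()}).sort_index()
    cell_means.index.names = ["species", "attribute"]
    species_means = cell_means.groupby(level="species").mean()
    return cell_means, species_means
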