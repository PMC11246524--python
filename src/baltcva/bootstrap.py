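"""Bootstrap certainty of vulnerability categories and direction classes.

Expert tally vectors are resampled with replacement within every
(species, attribute/factor) cell, the whole scoring pipeline is rerun
per replicate (weighted mean -> numeric sensitivity -> exposure ->
vulnerability -> category), and certainty is the modal category's
relative frequency across replicates.  Unanimous panels (or single-
expert cells) therefore yield certainty 1 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ExpertPanel
from .scoring import (
    CATEGORIES,
    DIRECTION_CLASSES,
    NEUTRAL_BAND,
    CategoryScale,
    DEFAULT_SCALE,
)

log = logging.getLogger(__name__)

_RANKS4 = np.arange(1.0, 5.0)
_WEIGHTS3 = np.array([-1.0, 0.0, 1.0])


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 1000
    seed: int = 0
    resampling_unit: str = "expert_tallies"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.resampling_unit != "expert_tallies":
            raise ValueError(f"unknown resampling unit {self.resampling_unit!r}")


@dataclass
class CertaintyResult:
    """Replicate category frequencies and modal-frequency certainty."""

    frequencies: pd.DataFrame  # species x category, rows sum to 1
    certainty: pd.Series       # species -> modal frequency in [0, 1]
    modal_category: pd.Series  # species -> modal category label

    @classmethod
    def from_labels(cls, labels: dict[str, np.ndarray], categories) -> "CertaintyResult":
        rows = {}
        for sp, lab in labels.items():
            counts = pd.Series(lab).value_counts()
            rows[sp] = [counts.get(c, 0) / len(lab) for c in categories]
        freq = pd.DataFrame.from_dict(rows, orient="index", columns=list(categories)).sort_index()
        return cls(
            frequencies=freq,
            certainty=freq.max(axis=1),
            modal_category=freq.idxmax(axis=1),
        )


def _cell_replicate_scores(counts: np.ndarray, idx: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Weighted-mean score per replicate for one cell.

    counts: (n_experts, n_bins); idx: (n_boot, n_experts) resampled
    expert indices; returns (n_boot,) scores.
    """
    pooled = counts[idx].sum(axis=1)  # (n_boot, n_bins)
    return pooled @ ranks / pooled.sum(axis=1)


def _resampled_matrix(panel: ExpertPanel, species: list[str], n_boot: int,
                      rng: np.random.Generator, ranks: np.ndarray) -> dict[str, np.ndarray]:
    """Per species: (n_boot, n_cells) replicate scores of 4-bin cells.

    Cells are visited in sorted (species, attribute) order so a fixed
    seed gives bit-identical replicates; replicate r uses row r of every
    cell's resample block, keeping replicates exchangeable.
    """
    cells = panel.cells()
    out: dict[str, list[np.ndarray]] = {sp: [] for sp in species}
    for (sp, attr) in sorted(cells):
        if sp not in out:
            continue
        counts = np.stack([t.as_array() for t in cells[(sp, attr)]])
        n_exp = counts.shape[0]
        idx = rng.integers(0, n_exp, size=(n_boot, n_exp))
        out[sp].append(_cell_replicate_scores(counts, idx, ranks))
    return {sp: np.column_stack(v) for sp, v in out.items() if v}


def bootstrap_vulnerability(panel_sens: ExpertPanel, panel_expo: ExpertPanel,
                            cfg: BootstrapConfig,
                            mode: str = "geometric_mean",
                            scale: CategoryScale = DEFAULT_SCALE) -> CertaintyResult:
    """Certainty of the vulnerability category per species.

    Sensitivity and exposure panels are resampled independently; species
    present in only one panel are excluded with a warning.
    """
    panel_sens.validate()
    panel_expo.validate()
    sens_species = set(panel_sens.species)
    expo_species = set(panel_expo.species)
    shared = sorted(sens_species & expo_species)
    dropped = sorted(sens_species ^ expo_species)
    if dropped:
        log.warning("species present in one panel only, excluded: %s", dropped)
    if not shared:
        raise ValueError("sensitivity and exposure panels share no species")

    rng = np.random.default_rng(cfg.seed)
    sens_scores = _resampled_matrix(panel_sens, shared, cfg.n_boot, rng, _RANKS4)
    expo_scores = _resampled_matrix(panel_expo, shared, cfg.n_boot, rng, _RANKS4)

    labels: dict[str, np.ndarray] = {}
    cat_lowers = np.array([scale.lower_bounds[c] for c in ("M", "H", "VH")])
    for sp in shared:
        s = sens_scores[sp].mean(axis=1)  # numeric sensitivity per replicate
        e = expo_scores[sp].mean(axis=1)
        if mode == "geometric_mean":
            v = np.sqrt(s * e)
        elif mode == "product":
            v = s * e
        else:
            raise ValueError(f"unknown vulnerability mode {mode!r}")
        # digitize against the category lower bounds: 0->L, 1->M, 2->H, 3->VH
        codes = np.searchsorted(cat_lowers, v, side="right")
        labels[sp] = np.array(CATEGORIES)[codes]
    return CertaintyResult.from_labels(labels, CATEGORIES)


def bootstrap_direction(panel: ExpertPanel, cfg: BootstrapConfig) -> CertaintyResult:
    """Certainty of the direction class per species, same resampling scheme."""
    if not panel.directional:
        raise ValueError("panel holds no directional tallies")
    rng = np.random.default_rng(cfg.seed)
    labels: dict[str, np.ndarray] = {}
    for sp in sorted({k[1] for k in panel.directional}):
        counts = np.stack([t.as_array() for t in panel.species_directions(sp)])
        n_exp = counts.shape[0]
        idx = rng.integers(0, n_exp, size=(cfg.n_boot, n_exp))
        pooled = counts[idx].sum(axis=1)
        de = pooled @ _WEIGHTS3 / pooled.sum(axis=1)
        lab = np.full(de.shape, "neutral", dtype=object)
        lab[de < -NEUTRAL_BAND] = "negative"
        lab[de > NEUTRAL_BAND] = "positive"
        labels[sp] = lab
    return CertaintyResult.from_labels(labels, DIRECTION_CLASSES)
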