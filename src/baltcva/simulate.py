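"""Synthetic study inputs with known ground truth.

The elicitation, the climate projections and the survey hauls of the
assessment are not deposited, so every pipeline input is emulated here
with controllable truth: expert panels drawn multinomially around known
true categories with a single consensus dial, temperature decades with
known per-cell warming and interannual variability, and haul clouds
with known spatial hotspots.  Synthetic outputs use exactly the schemas
the pipeline consumes, so synthetic and real data are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exposure import TemperatureCube
from .idw import GridSpec
from .panel import ExpertPanel
from .scoring import CATEGORY_RANK, DIRECTION_CLASSES
from .tallies import DIRECTION_BUDGET, SENSITIVITY_BUDGET

#: study conditions: panel sizes of the original elicitation
N_SENSITIVITY_EXPERTS = 20
N_EXPOSURE_EXPERTS = 6

_DIRECTION_RANK = {"negative": 0, "neutral": 1, "positive": 2}


def _ordinal_kernel(true_rank: int, n_bins: int, consensus: float) -> np.ndarray:
    """Bin probabilities decaying exponentially with ordinal distance.

    p_j ∝ exp(-consensus * |j - true|): consensus -> 0 gives uniform
    bins, consensus -> inf a point mass on the true bin.
    """
    if consensus <= 0:
        raise ValueError("consensus must be > 0")
    dist = np.abs(np.arange(n_bins) - true_rank)
    p = np.exp(-consensus * dist)
    return p / p.sum()


@dataclass
class PanelSimConfig:
    """Ground truth and consensus level for a simulated expert panel."""

    n_experts: int
    species: list[str]
    attributes: list[str]
    true_category: dict[tuple[str, str], str]   # (species, attribute) -> L/M/H/VH
    consensus: float = 4.0
    true_direction: dict[str, str] = field(default_factory=dict)  # species -> class
    quality_probs: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)       # P(quality = 0..3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.consensus <= 0:
            raise ValueError("consensus must be > 0")
        missing = [
            (s, a) for s in self.species for a in self.attributes
            if (s, a) not in self.true_category
        ]
        if missing:
            raise ValueError(f"true_category incomplete; first missing cells: {missing[:3]}")
        bad = set(self.true_category.values()) - set(CATEGORY_RANK)
        if bad:
            raise ValueError(f"invalid true categories {sorted(bad)}")
        bad_dir = set(self.true_direction.values()) - set(DIRECTION_CLASSES)
        if bad_dir:
            raise ValueError(f"invalid true directions {sorted(bad_dir)}")


def simulate_panel(cfg: PanelSimConfig) -> ExpertPanel:
    """Draw an expert panel around the configured truth.

    Each expert's 5 tallies per cell are multinomial over the ordinal
    kernel centred on the true bin; direction tallies are 4 multinomial
    draws over 3 bins; data quality is i.i.d. from ``quality_probs``.
    Deterministic under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = ExpertPanel()
    experts = [f"E{i + 1:02d}" for i in range(cfg.n_experts)]
    for sp in cfg.species:
        for attr in cfg.attributes:
            true = cfg.true_category[(sp, attr)]
            p = _ordinal_kernel(CATEGORY_RANK[true] - 1, 4, cfg.consensus)
            draws = rng.multinomial(SENSITIVITY_BUDGET, p, size=cfg.n_experts)
            quals = rng.choice(4, size=cfg.n_experts, p=cfg.quality_probs)
            for ex, counts, q in zip(experts, draws, quals):
                panel.add_tally(ex, sp, attr, tuple(int(c) for c in counts))
                panel.add_quality(ex, sp, attr, int(q))
        if sp in cfg.true_direction:
            p3 = _ordinal_kernel(_DIRECTION_RANK[cfg.true_direction[sp]], 3, cfg.consensus)
            draws = rng.multinomial(DIRECTION_BUDGET, p3, size=cfg.n_experts)
            for ex, counts in zip(experts, draws):
                panel.add_direction(ex, sp, tuple(int(c) for c in counts))
    return panel


@dataclass
class ClimateSimConfig:
    """Grid, reference climate and warming signal for simulated decades.

    ``ref_mean``, ``sigma`` and ``warming`` may be scalars or (nlat,
    nlon) fields; ``sigma`` is the interannual SD so the expected cell
    |Z| of a (reference, future) pair is warming/sigma.
    """

    nlat: int = 40
    nlon: int = 40
    ref_mean: float | np.ndarray = 8.0
    sigma: float | np.ndarray = 1.0
    warming: dict[str, float | np.ndarray] = field(
        default_factory=lambda: {"RCP45_MOC": 0.5, "RCP45_EOC": 1.0, "RCP85_EOC": 2.5}
    )
    lat0: float = 54.0
    lon0: float = 10.0
    resolution: float = 0.05
    depth_layer: str = "bottom"
    season: str = "annual"
    mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("interannual sigma must be > 0 on unmasked cells")


_DECADE_YEARS = {
    "reference": range(2010, 2020),
    "RCP45_MOC": range(2040, 2050),
    "RCP45_EOC": range(2080, 2090),
    "RCP85_EOC": range(2080, 2090),
}


def simulate_temperature_cube(cfg: ClimateSimConfig, decade: str = "reference") -> TemperatureCube:
    """One simulated decade: mean field (+ warming if future) + noise.

    ``decade`` is ``"reference"`` or one of the scenario tags in
    ``cfg.warming``; each cell-year value is Gaussian around the cell
    mean with SD sigma.  The seed is offset per decade tag so reference
    and future draws are independent but jointly reproducible.
    """
    if decade != "reference" and decade not in cfg.warming:
        raise ValueError(f"unknown decade tag {decade!r}")
    delta = 0.0 if decade == "reference" else cfg.warming[decade]
    years = np.array(list(_DECADE_YEARS.get(decade, range(2080, 2090))))
    offset = 0 if decade == "reference" else 1 + sorted(cfg.warming).index(decade)
    rng = np.random.default_rng(cfg.seed + offset)
    shape = (years.size, cfg.nlat, cfg.nlon)
    base = np.broadcast_to(np.asarray(cfg.ref_mean, dtype=float), (cfg.nlat, cfg.nlon))
    dT = np.broadcast_to(np.asarray(delta, dtype=float), (cfg.nlat, cfg.nlon))
    sig = np.broadcast_to(np.asarray(cfg.sigma, dtype=float), (cfg.nlat, cfg.nlon))
    values = base + dT + rng.standard_normal(shape) * sig
    if cfg.mask is not None:
        values = np.where(cfg.mask[None, :, :], np.nan, values)
    lats = cfg.lat0 + cfg.resolution * (np.arange(cfg.nlat) + 0.5)
    lons = cfg.lon0 + cfg.resolution * (np.arange(cfg.nlon) + 0.5)
    da = xr.DataArray(values, coords={"year": years, "lat": lats, "lon": lons},
                      dims=("year", "lat", "lon"))
    return TemperatureCube(data=da, decade=decade, depth_layer=cfg.depth_layer,
                           season=cfg.season)


@dataclass(frozen=True)
class Hotspot:
    lat: float
    lon: float
    spread: float   # Gaussian bump SD, degrees
    peak: float     # CPUE at the hotspot center


def simulate_hauls(hotspots: list[Hotspot], n_hauls: int, years,
                   grid: GridSpec, species: str = "cod", survey: str = "BITS",
                   noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Haul table with CPUE from Gaussian-bump hotspot intensities.

    Haul positions are uniform over the grid bounding box; CPUE at a
    haul is the summed hotspot intensity plus truncated-at-zero Gaussian
    noise.  Deterministic under seed.
    """
    if grid.lat_max <= grid.lat_min or grid.lon_max <= grid.lon_min:
        raise ValueError("empty spatial domain")
    rng = np.random.default_rng(seed)
    rows = []
    for year in years:
        lats = rng.uniform(grid.lat_min, grid.lat_max, size=n_hauls)
        lons = rng.uniform(grid.lon_min, grid.lon_max, size=n_hauls)
        cpue = np.zeros(n_hauls)
        for h in hotspots:
            d2 = (lats - h.lat) ** 2 + (lons - h.lon) ** 2
            cpue += h.peak * np.exp(-d2 / (2 * h.spread ** 2))
        if noise_sd > 0:
            cpue = np.maximum(cpue + rng.normal(0, noise_sd, size=n_hauls), 0.0)
        for la, lo, c in zip(lats, lons, cpue):
            rows.append({"survey": survey, "year": int(year), "lat": la,
                         "lon": lo, "species": species, "cpue": c})
    return pd.DataFrame(rows, columns=["survey", "year", "lat", "lon", "species", "cpue"])


def default_true_categories(species, attributes, seed: int = 0,
                            probs=(0.25, 0.35, 0.25, 0.15)) -> dict[tuple[str, str], str]:
    """A reproducible random truth map over a species x attribute grid."""
    rng = np.random.default_rng(seed)
    cats = np.array(["L", "M", "H", "VH"])
    return {
        (s, a): str(rng.choice(cats, p=probs))
        for s in species for a in attributes
    }


def stratified_true_categories(species, attribute: str, probs,
                               seed: int = 0) -> dict[tuple[str, str], str]:
    """Truth map for one factor with category counts fixed to the mix.

    Counts follow largest-remainder rounding of ``probs * n_species`` and
    are shuffled across species under the seed, so the panel-mean score
    tracks the mix's expected mean instead of fluctuating with i.i.d.
    category draws.
    """
    cats = ["L", "M", "H", "VH"]
    probs = np.asarray(probs, dtype=float)
    if probs.size != 4 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be 4 category probabilities summing to 1")
    n = len(species)
    ideal = probs * n
    counts = np.floor(ideal).astype(int)
    for i in np.argsort(-(ideal - counts))[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(cats, counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return {(s, attribute): str(c) for s, c in zip(species, labels)}
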