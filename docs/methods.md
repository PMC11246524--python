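# Methods

## Scope and data model

The package implements a trait-based, expert-elicitation climate
vulnerability assessment (CVA) for a 22-species fish community. The
atoms of the elicitation are tallies: each expert spreads a fixed
budget of 5 tallies over the four ordinal bins L/M/H/VH for every
species × sensitivity-attribute cell (and for each exposure factor),
and 4 tallies over negative/neutral/positive bins for the directional
effect of climate change on each species. Spreading the budget encodes
the expert's own uncertainty. Data quality is rated 0–3 per cell
(3 = adequate data, 0 = none). The packaged species roster (22 species
with ecotype: 15 marine, 2 anadromous, 1 catadromous, 4
freshwater-brackish) and the 12-attribute table with their low/high
scoring anchors ship as CSV transcriptions under `baltcva/data/`.

## Scoring

**Weighted mean (per cell).** Tallies are pooled (summed bin-wise)
across the panel and scored as
`X = (L·1 + M·2 + H·3 + VH·4)/(L+M+H+VH)`, a value in [1, 4]. Pooling
before averaging is equivalent to a tally-count-weighted mean of
per-expert scores and is the unique reading under which the
denominator is meaningful for a whole panel. The score equals the
expectation of the bin-rank distribution implied by the pooled counts;
the test suite verifies this exhaustively for all totals ≤ 20.

**Species sensitivity.** Two summaries are computed in parallel:

- *numeric*: the unweighted arithmetic mean of the 12 attribute
  scores. No published attribute weights exist, so equal weights are
  the default; an explicit weight vector is accepted. Up to 2 missing
  attributes are tolerated (mean over the present ones, logged); more
  are an error. Missing cells are reported, never imputed.
- *logic rule*: VH when ≥ 3 attributes have mean ≥ 3.5, else H when
  ≥ 2 have mean ≥ 3.0, else M when ≥ 2 have mean ≥ 2.5, else L.
  Precedence VH > H > M > L (first match wins) is forced: any VH row
  also satisfies the H clause.

**Numeric categorization.** The printed breakpoints (VH ≥ 3.25,
H = 2.50–3.25, M = 1.75–2.49, L = 1.00–1.74) overlap at 3.25 and leave
1.74–1.75 and 2.49–2.50 unassigned; the implementation uses
lower-closed half-open intervals L [1, 1.75), M [1.75, 2.5),
H [2.5, 3.25), VH [3.25, 4], which reproduces every printed inequality
and maps every score in [1, 4] to exactly one category.

**Directional effects.** `DE = (Pos·1 + Neu·0 + Neg·(−1))/(Pos+Neu+Neg)`
in [−1, 1]; the neutral band is the closed interval [−0.333, 0.333]
using the literal printed decimal (not 1/3), with strict inequalities
outside.

**Vulnerability.** Sensitivity and exposure are combined
multiplicatively. The raw product ranges to 16, while the
categorization thresholds and reported scenario means live on the 1–4
scale; the default mode is therefore the geometric mean √(s·e), which
is symmetric, monotone in each argument, bounded in [1, 4] and
directly categorizable. The raw product is retained as an explicit
mode (`product`) that is not passed to the categorizer. Whether the
original assessment rescaled its product differently cannot be
determined from what is printed; both modes are exposed and the choice
is documented rather than resolved.

## Exposure mapping

Temperature decades are per-cell, per-year means on a cell-center
registered 0.05° × 0.05° grid. Decadal reductions use the arithmetic
mean and the sample SD (ddof = 1; the divisor convention is not
printed anywhere, n−1 is the conservative default and configurable).
The exposure statistic is `|Z| = |X̄_f − X̄_r|/σ_r`; the sign of change
is deliberately discarded. Cells with σ_r = 0 score |Z| = 0 when the
means agree and +∞ (flagged, binned very_high) otherwise — any finite
change against zero reference variability is maximal surprise. Bins:
low |Z| ≤ 0.5 < moderate ≤ 1.5 < high ≤ 2.0 < very_high.

Species distributions are gridded from haul CPUE by inverse distance
weighting over the k nearest hauls per year, with per-cell medians over
years. Defaults power = 2, k = 12, distance floor 10⁻⁶° are standard
geostatistical practice (none are printed) and config-exposed.
Distances are computed in degree space with a cos(latitude) correction
on longitude, matching the grid's anisotropic ~3 × 6 km cells. A haul
within the distance floor of a cell center takes the cell exactly, so
the interpolation is exact at haul locations and bounded by the hull
of contributing haul values. `overlap_summary` reports the
CPUE-weighted fraction of a distribution in each exposure bin — the
quantitative counterpart of the human overlap judgement that informed
the exposure scoring.

## Bootstrap certainty

Certainty of a species' vulnerability category (and direction class)
is the modal-category relative frequency over n_boot = 1000 replicates.
Each replicate independently resamples expert tally vectors with
replacement within every (species, cell) of both panels — the finest
unit consistent with resampling "scores" — then reruns the full
pipeline (pooled weighted mean → numeric sensitivity → exposure →
vulnerability → category). Unanimous panels and single-expert cells
yield certainty exactly 1 by construction. Sensitivity and exposure
panels are resampled independently (the panels had different expert
groups); joint resampling would be a config extension. Randomness
comes from one generator seeded from the config; cells are visited in
sorted order and each draws its full (n_boot × n_experts) index block,
replicate r consuming row r of every block, so replicates are
exchangeable and runs are bit-reproducible. For 2–3-expert panels the
replicate distribution is checked against exhaustive enumeration of
all resample outcomes.

## Community structure

Clustering and PCA run on the species × attribute score matrix with
columns standardized to unit variance (constant columns left unscaled);
distance Euclidean, linkage Ward; the species dendrogram is cut at
k = 4 groups. None of these choices are printed for the original
figure; they are the common defaults for trait heatmaps and are
config-exposed, and the original group memberships are not asserted
anywhere (the underlying tallies are not deposited). PCA fixes each
component's sign so its largest-magnitude attribute loading is
positive, making biplots reproducible.

## Synthetic data

The generators define the study conditions:

- **Panels**: 20 sensitivity experts and 6 exposure experts (the
  original panel sizes). For a cell with true bin t, bin probabilities
  follow the ordinal kernel p_j ∝ exp(−c·|j − t|) with one consensus
  dial c (default 4.0): c → ∞ is unanimity, c → 0 uniform tallies.
  Tallies are multinomial draws of the 5 (or 4) budget units; data
  quality is i.i.d. over {0..3}.
- **Exposure truth per scenario**: category counts over the 22 species
  are fixed by largest-remainder allocation of the scenario mix and
  shuffled under the seed. The default mixes make the expected
  scenario-mean exposure 1.2 (RCP 4.5 mid-century), 1.5 (RCP 4.5
  end-of-century) and 2.2 (RCP 8.5 end-of-century) — the scenario
  means the assessment reports.
- **Climate cubes**: cell-year values are the reference mean field
  (+ warming ΔT for future decades) plus Gaussian noise with
  interannual SD σ, so the expected cell |Z| is ΔT/σ. Ten-year decades
  mean |Z| carries substantial sampling noise (the reference SD is
  estimated from 10 values); with ΔT = σ the cell majority is
  moderate, with ΔT = 3σ nearly all cells are very_high.
- **Hauls**: uniform positions with CPUE from Gaussian-bump hotspot
  intensities plus truncated noise.

What the synthetic data does *not* emulate: spatial covariance of real
climate-model output, expert bias/correlation structure, survey design
effects (hauls are uniform, real surveys are stratified), or seasonal
migration. Passing recovery tests therefore demonstrates correctness
of the machinery under known truth, not fidelity of the original
expert judgements.

## Numerical notes and edge cases

- Tally validation rejects wrong budget sums, negative and non-integer
  counts, naming the offending (expert, species, attribute) cell.
- The logic rule has knife-edge behavior by construction: true
  attribute ranks 3 and 4 sit exactly on its closed ≥ 3.0 / ≥ 3.5
  boundaries, so with finite panels a species' category can flip on
  arbitrarily small downward noise in a boundary attribute. Cell-level
  category recovery at the default consensus exceeds 95%; exact
  species-level logic-rule agreement is a near-unanimity limit
  property.
- Bootstrap category frequencies use `searchsorted` on the category
  lower bounds, consistent bit-for-bit with the scalar categorizer.
- Certainty-vs-consensus monotonicity holds averaged over the full
  22 × 12 grid; on very small grids low-consensus panels can show
  deceptively high certainty because near-uniform pooled tallies
  concentrate scores tightly around 2.5.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); there is no global random state.

## Problem sizes

Default runs use the full 22 × 12 grid with 20/6 experts and
n_boot = 1000; recovery and exposure checks use ≥ 1000 grid cells
(32 × 32); the IDW exactness check uses a 200 × 200 grid (0.01°) with
60 hauls. A complete pipeline run takes a few seconds on one core.
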