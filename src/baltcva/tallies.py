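"""Tally primitives of the expert elicitation.

Each expert expresses a judgement on a species x attribute (or exposure
factor) cell by distributing a fixed budget of tallies across ordinal
bins: five tallies over four sensitivity/exposure bins (low, moderate,
high, very high), and four tallies over three directional-effect bins
(negative, neutral, positive).  Spreading the budget expresses the
expert's own uncertainty; piling it on one bin expresses conviction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SENSITIVITY_BINS: tuple[str, ...] = ("L", "M", "H", "VH")
DIRECTION_BINS: tuple[str, ...] = ("Neg", "Neu", "Pos")

#: tallies each expert distributes on a 4-bin (sensitivity/exposure) scale
SENSITIVITY_BUDGET = 5
#: tallies each expert distributes on the 3-bin directional scale
DIRECTION_BUDGET = 4


class TallyError(ValueError):
    """A tally violates the fixed-budget scheme of the elicitation."""


@dataclass(frozen=True)
class SensitivityTally:
    """Bin counts (L, M, H, VH) of one expert for one cell; sums to 5.

    Also used for exposure-factor tallies, which follow the identical
    five-tallies-over-four-bins scheme.
    """

    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        validate_tally(self, SENSITIVITY_BUDGET)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class DirectionalTally:
    """Bin counts (Neg, Neu, Pos) of one expert for one species; sums to 4."""

    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        validate_tally(self, DIRECTION_BUDGET)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def validate_tally(tally, expected_total: int, context: str | None = None):
    """Check that a tally has non-negative integer counts summing to the budget.

    Parameters
    ----------
    tally
        A ``SensitivityTally``/``DirectionalTally`` or a plain count sequence.
    expected_total
        The tally budget: 5 for 4-bin scales, 4 for the 3-bin scale.
    context
        Optional "(expert, species, attribute)" text used in error messages.

    Returns
    -------
    The tally unchanged, if valid.
    """
    counts = getattr(tally, "counts", tally)
    where = f" in {context}" if context else ""
    for c in counts:
        if int(c) != c:
            raise TallyError(f"non-integer tally count {c!r}{where}")
        if c < 0:
            raise TallyError(f"negative tally count {c}{where}")
    total = int(sum(counts))
    if total != expected_total:
        raise TallyError(f"tally sum {total} ≠ {expected_total}{where}")
    return tally


def pool_tallies(tallies) -> np.ndarray:
    """Element-wise sum of per-expert bin counts for one cell.

    Pooling the raw counts before taking the weighted mean is equivalent
    to a tally-count-weighted mean of per-expert scores, and is the form
    in which the panel-level score denominator (total tally count) is
    meaningful.
    """
    tallies = list(tallies)
    if not tallies:
        raise TallyError("cannot pool an empty list of tallies")
    arrays = [np.asarray(getattr(t, "counts", t), dtype=float) for t in tallies]
    n_bins = {a.shape for a in arrays}
    if len(n_bins) != 1:
        raise TallyError("tallies with differing bin counts cannot be pooled")
    return np.sum(arrays, axis=0)
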