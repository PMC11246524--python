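"""Categorizers, directional effects, vulnerability and panel scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baltcva import (
    attribute_score_matrix,
    classify_direction,
    data_quality_summary,
    directional_effect,
    logic_rule_category,
    numeric_category,
    numeric_sensitivity,
    vulnerability_score,
)
from baltcva.scoring import CATEGORY_RANK, directional_effects

scores_in_range = st.floats(1.0, 4.0, allow_nan=False)


class TestNumericCategory:
    @pytest.mark.parametrize("score,expected", [
        (3.25, "VH"),   # VH >= 3.25
        (1.74, "L"),    # L = 1.00-1.74
        (2.50, "H"),    # H = 2.50-3.25
        (1.00, "L"),
        (1.75, "M"),
        (2.49, "M"),
        (4.00, "VH"),
        (3.24999, "H"),
    ])
    def test_printed_boundaries(self, score, expected):
        assert numeric_category(score) == expected

    @pytest.mark.parametrize("score", [0.99, 4.01, float("nan")])
    def test_out_of_scale_rejected(self, score):
        with pytest.raises(ValueError):
            numeric_category(score)

    @given(scores_in_range)
    @settings(max_examples=200, derandomize=True)
    def test_partitions_the_scale(self, score):
        """Every score in [1, 4] maps to exactly one category."""
        assert numeric_category(score) in ("L", "M", "H", "VH")


class TestLogicRule:
    @pytest.mark.parametrize("row,expected", [
        ((3.6, 3.5, 3.5) + (1.0,) * 9, "VH"),   # 3 attributes >= 3.5
        ((3.0, 3.0) + (1.0,) * 10, "H"),        # 2 attributes >= 3.0
        ((2.5, 2.5) + (1.0,) * 10, "M"),
        ((2.0,) * 12, "L"),                      # zero attributes >= 2.5
        ((2.6,) + (1.0,) * 11, "L"),             # a single attribute >= 2.5 is not enough
        ((3.5, 3.5) + (1.0,) * 10, "H"),         # only 2 >= 3.5 falls through to H
    ])
    def test_rule_clauses_and_precedence(self, row, expected):
        assert logic_rule_category(row) == expected

    @given(st.lists(scores_in_range, min_size=12, max_size=12),
           st.integers(0, 11), st.floats(0.0, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_every_attribute(self, row, idx, bump):
        """Raising any attribute score never lowers the species category."""
        raised = list(row)
        raised[idx] = min(4.0, raised[idx] + bump * (4.0 - raised[idx]))
        assert CATEGORY_RANK[logic_rule_category(raised)] >= CATEGORY_RANK[logic_rule_category(row)]


class TestNumericSensitivity:
    def test_constant_row(self):
        assert numeric_sensitivity([2.0] * 12) == pytest.approx(2.0)

    def test_symmetric_split(self):
        assert numeric_sensitivity([1.0] * 6 + [4.0] * 6) == pytest.approx(2.5)

    def test_direct_mean(self):
        row = (3.5, 3.5, 3.5) + (1.0,) * 9
        assert numeric_sensitivity(row) == pytest.approx(1.625)

    def test_tolerates_two_missing_with_warning(self, caplog):
        row = [2.0] * 10 + [np.nan, np.nan]
        with caplog.at_level("WARNING"):
            assert numeric_sensitivity(row) == pytest.approx(2.0)
        assert "missing" in caplog.text

    def test_three_missing_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            numeric_sensitivity([2.0] * 9 + [np.nan] * 3)

    def test_optional_weights(self):
        row = pd.Series({"a": 1.0, "b": 4.0})
        assert numeric_sensitivity(row, weights={"a": 3.0, "b": 1.0}) == pytest.approx(1.75)


class TestDirectionalEffect:
    @pytest.mark.parametrize("counts,expected", [
        ((4, 0, 0), -1.0),
        ((0, 4, 0), 0.0),
        ((1, 0, 3), 0.5),
    ])
    def test_known_values(self, counts, expected):
        assert directional_effect(counts) == pytest.approx(expected)

    def test_antisymmetric_exhaustively(self):
        """Swapping Neg and Pos negates the score, for every 3-bin tally of 4."""
        for neg, neu in itertools.product(range(5), repeat=2):
            pos = 4 - neg - neu
            if pos < 0:
                continue
            assert directional_effect((neg, neu, pos)) == pytest.approx(
                -directional_effect((pos, neu, neg)))

    @pytest.mark.parametrize("de,expected", [
        (-1.0, "negative"),
        (-0.333, "neutral"),   # boundary is inside the neutral band
        (0.333, "neutral"),
        (0.3331, "positive"),
        (-0.3331, "negative"),
        (0.75, "positive"),
    ])
    def test_classification_boundaries(self, de, expected):
        assert classify_direction(de) == expected


class TestVulnerability:
    @pytest.mark.parametrize("s,e,mode,expected", [
        (4.0, 4.0, "geometric_mean", 4.0),
        (1.0, 1.0, "geometric_mean", 1.0),
        (1.0, 1.0, "product", 1.0),
        (3.0, 1.5, "geometric_mean", np.sqrt(4.5)),
        (3.0, 1.5, "product", 4.5),
    ])
    def test_known_values(self, s, e, mode, expected):
        assert vulnerability_score(s, e, mode=mode) == pytest.approx(expected)

    def test_geometric_mean_categorizes_on_the_1_4_scale(self):
        assert numeric_category(vulnerability_score(3.0, 1.5)) == "M"

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            vulnerability_score(0.5, 2.0)
        with pytest.raises(ValueError):
            vulnerability_score(2.0, 4.5)

    @given(scores_in_range, scores_in_range, scores_in_range)
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_monotone_bounded(self, s, e, e2):
        v = vulnerability_score(s, e)
        assert v == pytest.approx(vulnerability_score(e, s))
        assert 1.0 <= v <= 4.0
        if e2 >= e:
            assert vulnerability_score(s, e2) >= v - 1e-12


class TestPanelScoring:
    def test_attribute_score_matrix_pools_across_experts(self, tiny_panel):
        m = attribute_score_matrix(tiny_panel)
        assert m.scores.loc["cod", "habitat"] == pytest.approx(2.5)  # (5,0,0,5) pooled
        assert m.scores.loc["herring", "habitat"] == pytest.approx(3.0)
        assert m.scores.loc["cod", "salinity"] == pytest.approx((2.4 + 2.0) / 2)
        assert (m.n_tallies == 10).all().all()

    def test_missing_species_row_flagged_not_filled(self, tiny_panel):
        m = attribute_score_matrix(tiny_panel, species=["cod", "herring", "sprat"])
        assert ("sprat", "habitat") in m.missing_cells()
        assert np.isnan(m.scores.loc["sprat"]).all()

    def test_directional_effects_table(self, tiny_panel):
        de = directional_effects(tiny_panel)
        # cod: pooled (7,1,0) -> -7/8; herring: pooled (0,4,4) -> 0.5
        assert de.loc["cod", "directional_effect"] == pytest.approx(-0.875)
        assert de.loc["cod", "direction_class"] == "negative"
        assert de.loc["herring", "directional_effect"] == pytest.approx(0.5)
        assert de.loc["herring", "direction_class"] == "positive"

    def test_data_quality_summary_means(self):
        from baltcva import ExpertPanel
        panel = ExpertPanel()
        panel.add_tally("E1", "cod", "habitat", (5, 0, 0, 0))
        for e, q in (("E1", 1), ("E2", 2), ("E3", 2)):
            panel.add_quality(e, "cod", "habitat", q)
        for e, q in (("E1", 0), ("E2", 3)):
            panel.add_quality(e, "cod", "prey", q)
        cells, species = data_quality_summary(panel)
        assert cells[("cod", "habitat")] == pytest.approx(5 / 3)
        assert cells[("cod", "prey")] == pytest.approx(1.5)
        # species mean averages the attribute means, not the raw scores
        assert species["cod"] == pytest.approx((5 / 3 + 1.5) / 2)
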