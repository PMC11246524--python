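"""Bootstrap certainty: degenerate cases, enumeration oracles, calibration."""

import itertools

import numpy as np
import pytest

from baltcva import (
    BootstrapConfig,
    ExpertPanel,
    bootstrap_direction,
    bootstrap_vulnerability,
    classify_direction,
    directional_effect,
    numeric_category,
    vulnerability_score,
    weighted_mean_score,
)
from baltcva.tallies import pool_tallies


def one_factor_panel(tallies, species="cod", attr="temperature"):
    panel = ExpertPanel()
    for i, t in enumerate(tallies):
        panel.add_tally(f"E{i + 1}", species, attr, t)
    return panel


class TestDegenerateCases:
    def test_unanimous_panels_have_certainty_one(self, unanimous_panel):
        expo = one_factor_panel([(5, 0, 0, 0)] * 3)
        res = bootstrap_vulnerability(unanimous_panel, expo, BootstrapConfig(n_boot=200, seed=1))
        assert res.certainty["cod"] == 1.0
        dres = bootstrap_direction(unanimous_panel, BootstrapConfig(n_boot=200, seed=1))
        assert dres.certainty["cod"] == 1.0
        assert dres.modal_category["cod"] == "negative"

    def test_single_expert_per_cell_is_deterministic(self):
        sens = one_factor_panel([(1, 2, 1, 1)], attr="habitat")
        expo = one_factor_panel([(0, 5, 0, 0)])
        res = bootstrap_vulnerability(sens, expo, BootstrapConfig(n_boot=300, seed=7))
        assert res.certainty["cod"] == 1.0

    def test_single_replicate_certainty_one(self, unanimous_panel):
        expo = one_factor_panel([(0, 0, 5, 0)] * 2)
        res = bootstrap_vulnerability(unanimous_panel, expo, BootstrapConfig(n_boot=1, seed=0))
        assert res.certainty["cod"] == 1.0

    def test_fixed_seed_bit_reproducible(self, unanimous_panel):
        sens = one_factor_panel([(5, 0, 0, 0), (0, 0, 0, 5), (1, 2, 1, 1)], attr="habitat")
        expo = one_factor_panel([(0, 5, 0, 0), (0, 0, 5, 0)])
        cfg = BootstrapConfig(n_boot=500, seed=11)
        r1 = bootstrap_vulnerability(sens, expo, cfg)
        r2 = bootstrap_vulnerability(sens, expo, cfg)
        assert r1.frequencies.equals(r2.frequencies)

    def test_disjoint_species_excluded_with_warning(self, caplog):
        sens = one_factor_panel([(5, 0, 0, 0)], species="cod", attr="habitat")
        sens.add_tally("E1", "sprat", "habitat", (0, 5, 0, 0))
        expo = one_factor_panel([(5, 0, 0, 0)], species="cod")
        with caplog.at_level("WARNING"):
            res = bootstrap_vulnerability(sens, expo, BootstrapConfig(n_boot=10, seed=0))
        assert list(res.certainty.index) == ["cod"]
        assert "excluded" in caplog.text


def enumerate_direction_distribution(tallies):
    """Exact resample distribution of the direction class for one cell."""
    n = len(tallies)
    freq = {}
    for pick in itertools.product(range(n), repeat=n):
        pooled = pool_tallies([tallies[i] for i in pick])
        cls = classify_direction(directional_effect(pooled))
        freq[cls] = freq.get(cls, 0) + 1
    total = n ** n
    return {k: v / total for k, v in freq.items()}


def enumerate_vulnerability_distribution(sens_tallies, expo_tallies):
    """Exact category distribution for a 1-attribute, 1-factor pipeline."""
    ns, ne = len(sens_tallies), len(expo_tallies)
    freq = {}
    for s_pick in itertools.product(range(ns), repeat=ns):
        s = weighted_mean_score(pool_tallies([sens_tallies[i] for i in s_pick]))
        for e_pick in itertools.product(range(ne), repeat=ne):
            e = weighted_mean_score(pool_tallies([expo_tallies[i] for i in e_pick]))
            cat = numeric_category(vulnerability_score(s, e))
            freq[cat] = freq.get(cat, 0) + 1
    total = ns ** ns * ne ** ne
    return {k: v / total for k, v in freq.items()}


class TestEnumerationOracles:
    def test_direction_frequencies_match_exact_enumeration(self):
        """Two opposed experts: the bootstrap distribution over the 2^2
        equally likely resamples is recovered within 3 Monte-Carlo SEs."""
        tallies = [(4, 0, 0), (0, 0, 4)]
        exact = enumerate_direction_distribution(tallies)
        panel = ExpertPanel()
        panel.add_tally("E1", "cod", "habitat", (5, 0, 0, 0))  # panel needs entries
        for i, t in enumerate(tallies):
            panel.add_direction(f"E{i + 1}", "cod", t)
        n_boot = 100_000
        res = bootstrap_direction(panel, BootstrapConfig(n_boot=n_boot, seed=5))
        for cls, p in exact.items():
            se = np.sqrt(p * (1 - p) / n_boot)
            assert abs(res.frequencies.loc["cod", cls] - p) <= 3 * se + 1e-12

    def test_vulnerability_frequencies_match_exact_enumeration(self):
        """Panel straddling a category boundary: bootstrap frequencies at
        n_boot = 1e5 match the 3-expert enumeration within 3 MC SEs."""
        sens_tallies = [(0, 0, 5, 0), (0, 0, 0, 5), (0, 5, 0, 0)]
        expo_tallies = [(0, 0, 5, 0), (0, 5, 0, 0)]
        exact = enumerate_vulnerability_distribution(sens_tallies, expo_tallies)
        assert len(exact) > 1  # truly astride a boundary
        sens = one_factor_panel(sens_tallies, attr="habitat")
        expo = one_factor_panel(expo_tallies)
        n_boot = 100_000
        res = bootstrap_vulnerability(sens, expo, BootstrapConfig(n_boot=n_boot, seed=9))
        for cat, p in exact.items():
            se = np.sqrt(p * (1 - p) / n_boot)
            assert abs(res.frequencies.loc["cod", cat] - p) <= 3 * se + 1e-12

    def test_frequencies_sum_to_one(self):
        sens = one_factor_panel([(1, 2, 2, 0), (0, 1, 2, 2)], attr="habitat")
        expo = one_factor_panel([(2, 3, 0, 0), (0, 0, 3, 2)])
        res = bootstrap_vulnerability(sens, expo, BootstrapConfig(n_boot=2000, seed=3))
        assert res.frequencies.sum(axis=1)["cod"] == pytest.approx(1.0)
        assert res.certainty["cod"] >= 0.25  # at least 1/|categories|


class TestCalibration:
    def test_certainty_increases_with_consensus(self):
        """Mean certainty is non-decreasing along a consensus ladder."""
        from baltcva import PanelSimConfig, simulate_panel
        from baltcva.simulate import default_true_categories

        from baltcva import ATTRIBUTE_KEYS, load_species_roster

        species = list(load_species_roster()["common_name"])
        attrs = list(ATTRIBUTE_KEYS)
        truth = default_true_categories(species, attrs, seed=0)
        expo_truth = default_true_categories(species, ["temperature"], seed=1)
        means = []
        for consensus in (0.5, 2.0, 8.0):
            sens = simulate_panel(PanelSimConfig(
                n_experts=20, species=species, attributes=attrs,
                true_category=truth, consensus=consensus, seed=2))
            expo = simulate_panel(PanelSimConfig(
                n_experts=6, species=species, attributes=["temperature"],
                true_category=expo_truth, consensus=consensus, seed=3))
            res = bootstrap_vulnerability(sens, expo, BootstrapConfig(n_boot=400, seed=4))
            means.append(res.certainty.mean())
        assert means[0] <= means[1] <= means[2]
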