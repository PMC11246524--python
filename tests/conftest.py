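import numpy as np
import pytest

from baltcva import ExpertPanel, GridSpec


@pytest.fixture
def tiny_panel() -> ExpertPanel:
    """Two experts, two species, two attributes, with direction + quality."""
    panel = ExpertPanel()
    panel.add_tally("E1", "cod", "habitat", (5, 0, 0, 0))
    panel.add_tally("E2", "cod", "habitat", (0, 0, 0, 5))
    panel.add_tally("E1", "cod", "salinity", (1, 2, 1, 1))
    panel.add_tally("E2", "cod", "salinity", (0, 5, 0, 0))
    panel.add_tally("E1", "herring", "habitat", (0, 0, 5, 0))
    panel.add_tally("E2", "herring", "habitat", (0, 0, 5, 0))
    panel.add_tally("E1", "herring", "salinity", (5, 0, 0, 0))
    panel.add_tally("E2", "herring", "salinity", (5, 0, 0, 0))
    panel.add_direction("E1", "cod", (4, 0, 0))
    panel.add_direction("E2", "cod", (3, 1, 0))
    panel.add_direction("E1", "herring", (0, 0, 4))
    panel.add_direction("E2", "herring", (0, 4, 0))
    for e in ("E1", "E2"):
        for sp in ("cod", "herring"):
            for attr in ("habitat", "salinity"):
                panel.add_quality(e, sp, attr, 2)
    return panel


@pytest.fixture
def unanimous_panel() -> ExpertPanel:
    """Every expert gives the identical tally in every cell."""
    panel = ExpertPanel()
    for e in ("E1", "E2", "E3"):
        panel.add_tally(e, "cod", "habitat", (0, 0, 0, 5))
        panel.add_tally(e, "cod", "temperature", (0, 5, 0, 0))
        panel.add_direction(e, "cod", (4, 0, 0))
    return panel


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(lat_min=54.0, lat_max=55.0, lon_min=10.0, lon_max=11.0, resolution=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
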