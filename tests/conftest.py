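import numpy as np
import pytest

from asymdiv.io_core import Annotation, RegionBox
from asymdiv.synthetic import (
    DivisionSceneConfig,
    FixedCellSpec,
    simulate_division_movie,
    simulate_fixed_cell,
)


@pytest.fixture(scope="session")
def division_scene():
    """One default-noise division movie with ground truth."""
    config = DivisionSceneConfig(seed=11)
    movie, truth = simulate_division_movie(config)
    return config, movie, truth


@pytest.fixture(scope="session")
def annotation():
    return Annotation(anterior_direction=(0.0, 1.0),
                      blank_region=RegionBox((0, 0), (16, 16)))


MIXED_ZONE_COUNTS = {"central": {("Par3",): 3, ("Dlic1",): 2, ("Par3", "Dlic1"): 5}}


@pytest.fixture(scope="session")
def mixed_fixed_scene():
    """Fixed cell with 3 Par3-only / 2 Dlic1-only / 5 both in the central zone."""
    spec = FixedCellSpec(zone_counts=MIXED_ZONE_COUNTS)
    movie, truth = simulate_fixed_cell(spec, seed=5)
    return spec, movie, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
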