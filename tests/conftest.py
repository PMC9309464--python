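import numpy as np
import pytest

from evorescue.landscape import LandscapeGrid
from evorescue.population import default_species


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def species_pair():
    return default_species()


def make_grid(agc, **kwargs):
    """Grid from a nested list/array of AGC values."""
    return LandscapeGrid(np.asarray(agc, dtype=float), **kwargs)


@pytest.fixture
def uniform_grid():
    """7x7 grid of contact-zone forest (suitable for both species), K=8."""
    return make_grid(np.full((7, 7), 93.0))
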