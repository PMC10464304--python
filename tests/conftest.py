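import numpy as np
import pytest
from hypothesis import settings

from dualmark import synthetic_genome as sg

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim():
    """Default 5-Mb synthetic genome with planted double-mark structure."""
    genome = sg.GenomeSpec(seed=1)
    return sg.generate_tracks(genome)


@pytest.fixture(scope="session")
def small_sizes():
    return {"chrA": 10_000, "chrB": 5_000}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
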