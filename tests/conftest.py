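import numpy as np
import pytest
from hypothesis import settings

import hetrack as h

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def parents() -> h.ParentalPair:
    """Two chromosome sets, ~200 diagnostic sites each."""
    return h.simulate_parents(2, 100_000, 0.002, seed=11)


@pytest.fixture(scope="session")
def balanced_map(parents) -> h.CompositionMap:
    return h.CompositionMap.uniform(parents.chrom_lengths)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
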