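import numpy as np
import pytest
from hypothesis import settings

import wavecnn as w

# derandomized hypothesis profile: property tests are reproducible
settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pairs():
    """A small mixed planar/spiral dataset for cheap training tests."""
    gen = np.random.default_rng(7)
    train, _ = w.generate_pairs(48, gen)
    test, _ = w.generate_pairs(16, gen)
    return train, test
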