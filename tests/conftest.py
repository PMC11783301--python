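import numpy as np
import pytest

from ssfa.synthetic import generate_phantom


@pytest.fixture
def ribbon():
    """Factory for axis-aligned rectangular ribbons (constant-width tubes)."""

    def make(shape=(64, 128), rows=(30, 37), cols=(5, 120)):
        m = np.zeros(shape, dtype=bool)
        m[rows[0]:rows[1], cols[0]:cols[1]] = True
        return m

    return make


@pytest.fixture(scope="session")
def phantom128():
    """One medium phantom shared by read-only tests."""
    return generate_phantom(11, size=128, n_trees=3, radius_range=(2, 6),
                            noise_sd=0.05)


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom(21, size=64, n_trees=2, radius_range=(1.5, 4),
                            noise_sd=0.05)
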