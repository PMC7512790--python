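import numpy as np
import pytest

from fcekl import NoiseSpec, add_noise, make_trin_phantom, make_two_value_phantom


@pytest.fixture
def two_value():
    return make_two_value_phantom()


@pytest.fixture
def trin():
    return make_trin_phantom()


@pytest.fixture
def noisy_two_value(two_value):
    """50x50 binary phantom with 20%-level Gaussian noise, fixed seed."""
    return add_noise(two_value, NoiseSpec("gaussian", 20.0, seed=7))


def random_simplex_rows(rng, n, s):
    """Dirichlet(1) rows: uniform on the probability simplex."""
    return rng.dirichlet(np.ones(s), size=n)
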