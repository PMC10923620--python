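import numpy as np
import pytest

from hccseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast-to-generate phantom spec used across tests."""
    return PhantomSpec(volume_shape=(32, 32, 8), liver_axes=(12.0, 10.0, 4.0),
                       lesion_radius_range=(2.5, 4.0), noise_sigma=0.02,
                       deformation_amplitude=1.0, seed=123)


@pytest.fixture(scope="session")
def tiny_case(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240228)
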