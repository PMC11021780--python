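import numpy as np
import pytest

from cascadeseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A 32³ noise-free phantom: exact compartment intensities."""
    spec = PhantomSpec(grid_shape=(32, 32, 32), radii=(8.0, 5.0, 2.5),
                       noise_sd=0.0, seed=11, case_id="clean")
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(grid_shape=(32, 32, 32), radii=(8.0, 5.0, 2.5),
                       noise_sd=8.0, seed=5, case_id="noisy")
    return generate_phantom(spec)
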