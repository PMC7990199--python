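import numpy as np
import pytest

from atquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_pair():
    """One default phantom pair, shared across tests (read-only)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_pair():
    """Noise-free phantom for closed-form checks."""
    spec = PhantomSpec(seed=3, noise_sd=0.0, residual_sd=0.0)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
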