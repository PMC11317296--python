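import numpy as np
import pytest

from lynsu.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic desk-scale phantom (32x128x128, 10% asymmetry)."""
    return generate_phantom(PhantomSpec(shape=(32, 128, 128), seed=42, asymmetry=0.10))


@pytest.fixture(scope="session")
def symmetric_phantom():
    return generate_phantom(PhantomSpec(shape=(32, 128, 128), seed=7, asymmetry=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
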