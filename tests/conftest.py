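import numpy as np
import pytest

from bonediff import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """48^3 baseline phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(shape=(48, 48, 48), seed=11))


@pytest.fixture(scope="session")
def midsize_phantom():
    """64^3 baseline phantom for registration tests."""
    return generate_phantom(PhantomSpec(shape=(64, 64, 64), seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
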