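import numpy as np
import pytest

from sblda import SBLDAParams
from sblda.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_params() -> SBLDAParams:
    return SBLDAParams()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom (slice, truth) — shared, treat as read-only."""
    return generate_phantom(PhantomSpec(seed=1, noise_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
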