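import numpy as np
import pytest

from fetalatlas.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free week-24 phantom at 48³ (shared, read-only)."""
    spec = PhantomSpec(ga_weeks=24.0, grid_size=48, noise_level=0.0, seed=0)
    vol, lab = generate_phantom(spec)
    return spec, vol, lab


@pytest.fixture(scope="session")
def noisy_phantom():
    """Speckled week-24 phantom at 48³ (shared, read-only)."""
    spec = PhantomSpec(ga_weeks=24.0, grid_size=48, noise_level=0.3, seed=7)
    vol, lab = generate_phantom(spec)
    return spec, vol, lab


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
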