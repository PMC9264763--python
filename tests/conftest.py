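import numpy as np
import pytest

from rsibreast import PhantomConfig, generate_patient_phantom

SMALL_GRID = (32, 32, 8)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Down-scaled phantom grid for fast unit tests."""
    return PhantomConfig(grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_patient_phantom(small_config, seed=11)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free phantom: the forward model is exactly invertible."""
    cfg = PhantomConfig(grid_shape=(24, 24, 8), noise_sigma=0.0)
    return generate_patient_phantom(cfg, seed=7)
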