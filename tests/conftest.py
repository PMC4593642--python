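import numpy as np
import pytest

from filosim.config import MotorBindingConfig, SimConfig
from filosim.io import make_fixture
from filosim.mechanics import FiberMaterial


@pytest.fixture(scope="session")
def motor() -> MotorBindingConfig:
    return MotorBindingConfig()


@pytest.fixture(scope="session")
def lattice():
    """Small deterministic cross-linked network (pore 1.0 μm, 5 μm box)."""
    return make_fixture("lattice-5um")


@pytest.fixture()
def lattice_copy(lattice):
    return lattice.copy()


@pytest.fixture(scope="session")
def material() -> FiberMaterial:
    return FiberMaterial.from_diameter(34.0, 1.0e6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture()
def base_config() -> SimConfig:
    return SimConfig(seed=42)
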