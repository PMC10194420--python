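import numpy as np
import pytest

from neuromap3d.phantom import PhantomConfig, PhantomData, make_phantom


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig(seed=7)


@pytest.fixture(scope="session")
def phantom_data(default_config) -> PhantomData:
    """One shared default phantom (2 peptides, 5 regions, 12 sections)."""
    return make_phantom(default_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230425)
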