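import numpy as np
import pytest

from vmap.labeling import BinScheme
from vmap.synthmap import (
    CohortConfig,
    ColorScale,
    PhantomConfig,
    generate_phantom,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def phantom(phantom_config):
    return generate_phantom(phantom_config, seed=7)


@pytest.fixture(scope="session")
def color_scale():
    return ColorScale()


@pytest.fixture(scope="session")
def bin_scheme():
    return BinScheme.equal()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six patients rendered at side 64: enough for IO and 5-fold plumbing."""
    return simulate_cohort(CohortConfig(n_patients=6, image_size=64), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
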