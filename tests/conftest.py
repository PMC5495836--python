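import numpy as np
import pytest

from oiconnect.datatypes import GroundTruth
from oiconnect.synthetic import default_coupling, make_cortex_mask, make_seed_atlas


@pytest.fixture(scope="session")
def small_mask():
    return make_cortex_mask(64, 64, 4)


@pytest.fixture(scope="session")
def small_atlas(small_mask):
    return make_seed_atlas(small_mask)


@pytest.fixture(scope="session")
def study_atlas():
    """Atlas at the emulated acquisition geometry (128 x 128 grid)."""
    return make_seed_atlas(make_cortex_mask(128, 128, 4))


@pytest.fixture(scope="session")
def control_truth(small_atlas):
    coupling = default_coupling(small_atlas.seed_names)
    return GroundTruth(
        coupling=coupling,
        seed_names=small_atlas.seed_names,
        group="control",
        rng_seed=123,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170704)
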