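import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from motioniq import BrainMask, StudyConfig, Volume, build_study, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def phantom_32():
    """A small deterministic phantom + mask shared across metric tests."""
    return make_phantom(shape=(32, 32, 32), seed=7, noise_sd=0.01)


@pytest.fixture(scope="session")
def small_study():
    """A three-subject miniature study for pipeline-level tests."""
    cfg = StudyConfig(n_subjects=3, shape=(32, 32, 32))
    return build_study(cfg, seed=11)


@pytest.fixture
def toy_volume():
    rng = np.random.default_rng(0)
    data = rng.random((12, 12, 12)) + 0.1
    return Volume(data=data, slice_axis=2, id="toy")


@pytest.fixture
def toy_mask(toy_volume):
    m = np.zeros(toy_volume.data.shape, dtype=np.uint8)
    m[3:9, 3:9, 2:10] = 1
    return BrainMask(data=m)
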