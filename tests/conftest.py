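import numpy as np
import pytest

from vrsa import assemble_U, make_fixture, sample_run
from vrsa.components import build_components


@pytest.fixture(scope="session")
def components():
    return build_components()


@pytest.fixture(scope="session")
def run_design():
    return sample_run(5)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Default tiny fixture: 4 subjects x 2 runs x 200 voxels, moderate planting."""
    return make_fixture("tiny", rng_seed=3)


@pytest.fixture(scope="session")
def tiny_strong_dataset():
    """Tiny fixture with a strongly planted gaze-target distance component."""
    return make_fixture("tiny", rng_seed=11, weights={"ET_dist": 4.0})


@pytest.fixture(scope="session")
def tiny_noise_dataset():
    """Tiny fixture with no planted components (pure voxel noise)."""
    return make_fixture("tiny", rng_seed=17, weights={})


def pooled(dataset):
    return [assemble_U(dataset.runs(s)) for s in dataset.subjects]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
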