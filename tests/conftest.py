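import numpy as np
import pytest

from woundmetric.scene_synthesis import (
    SceneSpec, render_scene, sample_scene_specs,
)


@pytest.fixture(scope="session")
def default_scene():
    return render_scene(SceneSpec())


@pytest.fixture(scope="session")
def scene_batch():
    """Twenty varied scenes used by the recovery checks."""
    return [render_scene(s) for s in sample_scene_specs(20, seed=0)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask_pair(rng, shape=(40, 40), p=0.35):
    """A pair of random blobs-ish masks for metric oracle checks."""
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    return a, b
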