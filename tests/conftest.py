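import numpy as np
import pytest

from hive.fixtures import FixtureSpec, make_image, make_labeled_set
from hive.records import ImageRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_image(rng):
    """A 64x64 seeded-noise image used by many extractor tests."""
    return make_image(FixtureSpec(kind="gaussian_noise", width=64, height=64,
                                  seed=7))


@pytest.fixture
def constant_image():
    return make_image(FixtureSpec(kind="constant", width=64, height=64,
                                  amplitude=0.5))


@pytest.fixture
def step_image():
    return make_image(FixtureSpec(kind="step_edge", width=64, height=64))


def random_record(rng, height, width) -> ImageRecord:
    return ImageRecord(f"rand_{height}x{width}", rng.random((height, width)))


@pytest.fixture(scope="session")
def small_labeled_dir(tmp_path_factory):
    """Six-image two-class texture directory with a labels CSV."""
    out = tmp_path_factory.mktemp("texture_set")
    labels = make_labeled_set(3, width=48, height=48, seed=11, out_dir=out)
    return out, labels
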