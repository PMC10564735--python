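import numpy as np
import pytest

from armnet import ImageRecord, SynthSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gray_record():
    """Constant mid-gray 64x64 image."""
    return ImageRecord(pixels=np.full((64, 64, 3), 128, dtype=np.uint8),
                       label="a", source_id="gray")


@pytest.fixture
def random_record(rng):
    return ImageRecord(
        pixels=rng.integers(0, 256, size=(48, 40, 3), dtype=np.uint8),
        label="b", source_id="rand")


@pytest.fixture(scope="session")
def small_dataset():
    """4 classes x 5 images of 64x64 synthetic faces."""
    return generate_dataset(SynthSpec(num_classes=4, images_per_class=5, seed=3))
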