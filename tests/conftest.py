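import numpy as np
import pytest

from osteoseg import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Nine 64x64 records (3/class) shared across read-only tests."""
    cfg = SynthConfig(
        image_height=64,
        image_width=64,
        n_images_per_class=3,
        tumor_size_range=(8, 20),
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
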