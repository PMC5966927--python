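import numpy as np
import pytest

from cxrtriage import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantoms():
    """A compact labelled phantom set shared across read-only tests."""
    cfg = PhantomConfig(image_size=64, n_normal=12, n_abnormal=6,
                        lesion_contrast=0.5, seed=11)
    return generate_dataset(cfg)
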