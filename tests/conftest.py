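import numpy as np
import pytest

from graftunet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 12-frame 64x64 synthetic dataset shared across read-only tests."""
    root = tmp_path_factory.mktemp("synth")
    cfg = SyntheticConfig(n_frames=12, frame_size=64, seed=5)
    index = generate_dataset(cfg, root / "images", root / "masks")
    return cfg, index, root
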