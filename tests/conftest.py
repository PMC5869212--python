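import numpy as np
import pytest

from greenmig.synthetic_data import make_fixture_bundle, tiny_config


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """Small on-disk study bundle (12 sites, 64x64 images)."""
    out = tmp_path_factory.mktemp("bundle")
    make_fixture_bundle(tiny_config(seed=5), out)
    return out


def gray_image(values01: np.ndarray) -> np.ndarray:
    """Stack a [0,1] intensity field into an 8-bit gray RGB image."""
    g = np.round(np.asarray(values01) * 255).astype(np.uint8)
    return np.repeat(g[:, :, None], 3, axis=2)
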