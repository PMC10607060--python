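import numpy as np
import pytest

from larvadet import render_scene, tiny_config, tiny_scene_spec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small in-memory dataset of 2-class 128x128 scenes."""
    data = []
    for i in range(6):
        img, boxes = render_scene(tiny_scene_spec(seed=500 + i))
        data.append((f"im{i}", np.asarray(img, dtype=np.float64) / 255.0, boxes))
    return data


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_config(seed=0)
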