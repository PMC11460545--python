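import numpy as np
import pytest

from woundkit.synthdata import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic scene with marker and a mixed-color wound."""
    return generate_scene(SceneSpec(seed=7, f_red=0.35, f_yellow=0.45, f_dark=0.05))


@pytest.fixture(scope="session")
def skin_scene_mask(default_scene):
    from woundkit.preprocess import skin_mask

    img, gt = default_scene
    return skin_mask(img)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
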