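import warnings

import numpy as np
import pytest

from cropstress.scene import SceneConfig, generate_scene
from cropstress.indices import compute_index_stack

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")


@pytest.fixture(scope="session")
def water_scene():
    cfg = SceneConfig(height_px=192, width_px=192, scenario="water", seed=11, noise_sd=0.0)
    scene, ref = generate_scene(cfg)
    return scene, ref, cfg


@pytest.fixture(scope="session")
def rust_scene():
    cfg = SceneConfig(height_px=192, width_px=192, scenario="rust", seed=11, noise_sd=0.0)
    scene, ref = generate_scene(cfg)
    return scene, ref, cfg


@pytest.fixture(scope="session")
def noisy_water_scene():
    cfg = SceneConfig(height_px=192, width_px=192, scenario="water", seed=3, noise_sd=0.02)
    scene, ref = generate_scene(cfg)
    return scene, ref, cfg


@pytest.fixture(scope="session")
def water_stack(water_scene):
    scene, _, _ = water_scene
    return compute_index_stack(scene)


@pytest.fixture(scope="session")
def rust_stack(rust_scene):
    scene, _, _ = rust_scene
    return compute_index_stack(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
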