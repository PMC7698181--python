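import numpy as np
import pytest

from funduslayers.pipeline import run_stages
from funduslayers.synth import SceneSpec, generate


@pytest.fixture(scope="session")
def scene():
    """One deterministic pathological synthetic scene."""
    img, truth = generate(SceneSpec(seed=5))
    return img, truth


@pytest.fixture(scope="session")
def stages(scene):
    """Full stage chain (preprocess … features) on the shared scene."""
    img, _ = scene
    return run_stages(img)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_fov_image(side=256, fov_frac=0.94, color=(0.7, 0.4, 0.12)):
    """Plain disk-FOV image helper used across test modules."""
    rows, cols = np.indices((side, side), dtype=float)
    center = side / 2.0
    radius = fov_frac * side / 2.0
    fov = np.hypot(rows - center, cols - center) <= radius
    img = np.where(fov[..., None], np.asarray(color), 0.0)
    return img, fov, 2.0 * radius
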