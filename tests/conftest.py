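import numpy as np
import pytest

from cabbagepose import SceneParams, generate_batch, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_blob(rng):
    """~200-pixel irregular blob mask."""
    mask = np.zeros((48, 48), dtype=bool)
    ys = rng.integers(8, 40, size=300)
    xs = rng.integers(8, 40, size=300)
    mask[ys, xs] = True
    # dilate a little so it is a connected-ish blob, not dust
    from scipy import ndimage

    return ndimage.binary_dilation(mask, iterations=1)


@pytest.fixture
def vertical_scene():
    """Clean upright scene: angle 0, no curvature/occlusion/noise."""
    return generate_scene(
        SceneParams(true_angle_deg=0.0, root_curvature=0.0,
                    occlusion_frac=0.0, noise_frac=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def mixed_batch():
    """Small mixed batch shared by evaluation-level tests."""
    return generate_batch(60, seed=0)
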