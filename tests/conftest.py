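import numpy as np
import pytest

from cornseednet.msimage import MultispectralImage
from cornseednet.synthetic import SceneSpec, generate_scene


SMALL_SPEC = SceneSpec(width=360, height=280, n_seeds=5, adhesion_prob=0.0,
                       seed_axis_range=(12, 20), rng_seed=11)


@pytest.fixture(scope="session")
def small_scene():
    """A small noise-on scene with 5 disjoint seeds and its ground truth."""
    return generate_scene(SMALL_SPEC)


@pytest.fixture(scope="session")
def adhesion_scene():
    """A scene with touching seeds (adhesion clusters) and ground truth."""
    spec = SceneSpec(width=420, height=320, n_seeds=6, adhesion_prob=0.6,
                     seed_axis_range=(12, 20), rng_seed=5)
    return generate_scene(spec)


def disk_image(shape=(200, 140), centers=((70, 60),), radius=15,
               background=230, level=90):
    """Synthetic B-darker-than-background image with filled disks, plus mask."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    mask = np.zeros((h, w), dtype=bool)
    for (r, c) in centers:
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2
    plane = np.full((h, w), background, dtype=np.uint8)
    plane[mask] = level
    return MultispectralImage(np.dstack([plane] * 4)), mask
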