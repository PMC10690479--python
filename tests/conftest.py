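import numpy as np
import pytest

import cargoquant as cq


@pytest.fixture
def small_scene_spec():
    """A compact fixed-cell scene: 3 interior nuclei with bright puncta."""
    return cq.SceneSpec(image_shape=(192, 192), n_cells=3,
                        nucleus_radius_px=10, puncta_per_cell=8,
                        puncta_intensity=(3000.0, 100.0),
                        puncta_sigma_px=1.3, dispersion_px=18.0,
                        background_level=100.0, noise_model="poisson",
                        seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_disk_image(shape, centers, radius, level=1000.0, background=100.0,
                    noise_sd=5.0, seed=0):
    """Bright disks on a flat noisy background (segmentation fixtures)."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, background)
    for cx, cy in centers:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2] += level
    return img + rng.normal(0, noise_sd, shape)
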