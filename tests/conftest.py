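import numpy as np
import pytest

from telocomb import DetectionConfig, DistributionSpec, SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_scene_spec():
    """A small, low-noise scene with well-separated fibers at 0.1 um/px."""
    return SceneSpec(
        image_height_px=512,
        image_width_px=512,
        pixel_size_um=0.1,
        n_fibers=15,
        length_dist=DistributionSpec("lognormal", 6.0, 2.5),
        fiber_width_px=3.0,
        psf_sigma_px=1.0,
        interstitial_fraction=0.0,
        orphan_fraction=0.0,
        seed=3,
    )


@pytest.fixture
def detection_config():
    return DetectionConfig()


def fiber_mask(shape, r0, r1, c, half_width=1):
    """Solid vertical bar mask helper."""
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c - half_width : c + half_width + 1] = True
    return m
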