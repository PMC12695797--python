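import numpy as np
import pytest

from orchardvision import pipeline as pl
from orchardvision import synth


@pytest.fixture(scope="session")
def default_cfg() -> pl.PipelineConfig:
    return pl.PipelineConfig()


@pytest.fixture(scope="session")
def clean_scene():
    """Small noiseless day scene with isolated red apples (no occlusion)."""
    spec = synth.SceneSpec(
        image_size=(240, 360),
        n_apples=3,
        apple_color="red",
        radius_range=(14.0, 20.0),
        depth_range=(800.0, 1100.0),
        max_overlap=0.0,
        lighting="day",
        brightness_jitter=0.0,
        noise_sigma=0.0,
        seed=5,
        cluster_fraction=0.0,
    )
    left, right, truth = synth.render_scene(spec)
    return spec, left, right, truth


@pytest.fixture(scope="session")
def clean_detection(clean_scene, default_cfg):
    spec, left, right, truth = clean_scene
    cfg = default_cfg.for_color("red")
    result = pl.detect_scene(left, right, cfg)
    return result, truth, cfg


def disc_image(shape=(64, 64), center=(32.0, 32.0), radius=15.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
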