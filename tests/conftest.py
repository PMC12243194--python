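import numpy as np
import pytest

from grainray import phantom as ph
from grainray import pipeline as pl
from grainray.preprocessing import Radiograph, normalize

SMALL_SHAPE = (420, 640)
I0 = 12000


def small_acquisition(noise_sd=0.0, rng_seed=0):
    return ph.AcquisitionModel(
        background_intensity_I0=I0,
        detector_shape=SMALL_SHAPE,
        noise_sd=noise_sd,
        rng_seed=rng_seed,
    )


@pytest.fixture(scope="session")
def single_grain():
    """One filled grain, axis-aligned, centered on a small detector."""
    return ph.GrainSpec(
        id=1,
        center_px=(60.0, 60.0),
        semi_axes_px=(14.0, 8.0),
        depth_semi_axis_px=7.0,
        orientation_rad=0.0,
        husk_thickness_px=1.6,
        mu_husk=0.012,
        mu_kernel=0.085,
    )


@pytest.fixture(scope="session")
def mixed_scene():
    """100-grain scene with all trait classes, noise-free."""
    mix = ph.TraitMix(
        chaffy=0.15, chalky=0.3,
        hrr={100: 0.2, 80: 0.2, 60: 0.2, 40: 0.2, 20: 0.2},
    )
    return ph.build_scene(100, mix, small_acquisition(), seed=7)


@pytest.fixture(scope="session")
def mixed_attenuation(mixed_scene):
    counts = ph.render_radiograph(mixed_scene)
    return normalize(Radiograph(pixels=counts), "auto")


@pytest.fixture(scope="session")
def mixed_analysis(mixed_scene):
    return pl.analyze_scene(mixed_scene)


@pytest.fixture(scope="session")
def chaffy_training():
    """Scene + fitted chaffiness bundle (scaler, pca, cluster model)."""
    mix = ph.TraitMix(chaffy=0.2)
    scene = ph.build_scene(100, mix, small_acquisition(noise_sd=30.0, rng_seed=10), seed=10)
    analysis = pl.analyze_scene(scene)
    return analysis, pl.train_chaffy(analysis)


def rasterized_disk(radius: int) -> set:
    """Pixel set of a filled digital disk centered at the origin."""
    r = int(np.ceil(radius))
    pts = set()
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            if i * i + j * j <= radius * radius:
                pts.add((i, j))
    return pts
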