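import numpy as np
import pytest

from litfield import (
    EquirectImage,
    SynthSceneSpec,
    synthetic_calibration,
)


@pytest.fixture(scope="session")
def small_cal():
    """A small synthetic camera: 96 px image circle, 200×200 raster."""
    return synthetic_calibration(radius_px=96)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def constant_image():
    """A uniform 1e16 radiance field on a 64×64 equirect raster."""
    m = 64
    return EquirectImage(
        pixels=np.full((m, m, 3), 1e16), valid=np.ones((m, m), dtype=bool)
    )


def lognormal_image(mu_lit, sigma_lit, size, seed=0):
    """Equirect image whose per-pixel lit values are N(mu, sigma), shared RGB."""
    g = np.random.default_rng(seed).standard_normal((size, size))
    pixels = np.repeat(
        (10.0 ** (mu_lit + sigma_lit * g))[..., None], 3, axis=-1
    )
    return EquirectImage(pixels=pixels, valid=np.ones((size, size), dtype=bool))


@pytest.fixture
def sloped_spec():
    """A generic piecewise-linear scene: brighter sky, dark horizon band."""
    return SynthSceneSpec(
        profiles={
            "red": [(-90.0, 13.8), (-10.0, 14.1), (0.0, 13.6), (10.0, 14.3), (90.0, 14.6)],
            "green": [(-90.0, 13.9), (-10.0, 14.2), (0.0, 13.7), (10.0, 14.5), (90.0, 14.9)],
            "blue": [(-90.0, 13.6), (-10.0, 13.9), (0.0, 13.8), (10.0, 14.8), (90.0, 15.2)],
        },
        sigma=0.25,
        name="sloped",
        seed=7,
    )
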