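import numpy as np
import pytest

from centrofish import RunConfig, SceneConfig, WashoutKinetics


@pytest.fixture
def scene_config():
    return SceneConfig()


@pytest.fixture
def noiseless_config():
    return SceneConfig(noise=False)


@pytest.fixture
def kinetics():
    return WashoutKinetics()


@pytest.fixture
def run_config():
    return RunConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def add_gaussian(image, center_px, sigma_px, amplitude):
    """Dense (unwindowed) Gaussian renderer used as a test-side oracle."""
    yy, xx = np.mgrid[0:image.shape[0], 0:image.shape[1]].astype(float)
    image += amplitude * np.exp(
        -((yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2)
        / (2 * sigma_px**2)
    )
    return image
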