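import numpy as np
import pytest

from sscmap import phantom

SMALL_WL = np.linspace(913.0, 2166.0, 60)


@pytest.fixture(scope="session")
def small_wavelengths():
    return SMALL_WL


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise ellipsoid scene on a small grid."""
    cfg = phantom.PhantomConfig(
        noise_sd=0.0, wavelength_axis=SMALL_WL, seed=7, grid_shape=(44, 44)
    )
    return phantom.make_phantom(cfg)


@pytest.fixture(scope="session")
def flat_scene():
    cfg = phantom.PhantomConfig(
        shape_mode="flat_disc", noise_sd=0.0, wavelength_axis=SMALL_WL,
        seed=7, grid_shape=(40, 40)
    )
    return phantom.make_phantom(cfg)


@pytest.fixture(scope="session")
def noisy_batch():
    """Small batch with moderate detector noise plus its reference table."""
    scenes = phantom.make_phantom_batch(
        8, seed=11, noise_sd=10.0, wavelength_axis=SMALL_WL,
        grid_shape=(40, 40)
    )
    refs = []
    for s in scenes:
        refs.extend(phantom.make_reference_table(s))
    return scenes, refs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
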