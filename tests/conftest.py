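import numpy as np
import pytest

from sicklescreen import synthetic as syn


@pytest.fixture(scope="session")
def small_slide_spec():
    """A single small FOV dense enough to contain a few dozen cells."""
    return syn.SlideSpec(n_fov=1, fov_px=128, cell_density=2500.0,
                         sickle_fraction=0.2, wbc_fraction=0.0,
                         platelet_fraction=0.0, seed=3)


@pytest.fixture(scope="session")
def small_fov(small_slide_spec):
    """(image, mask, cells) for the shared small FOV."""
    return syn.render_clean_smear(small_slide_spec)


@pytest.fixture(scope="session")
def textured_image(small_fov):
    return small_fov[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
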