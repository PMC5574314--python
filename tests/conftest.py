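import numpy as np
import pytest

from mitometrics.psf import PSFEstimate, FWHM_FACTOR
from mitometrics.ratiometrics import ChannelStack


@pytest.fixture(scope="session")
def nominal_psf() -> PSFEstimate:
    """The acquisition-configuration PSF used throughout: 0.4/1.4 µm FWHM."""
    return PSFEstimate.from_sigma(0.4 / FWHM_FACTOR, 1.4 / FWHM_FACTOR, n_beads_used=24)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_stack(green, red, pixel_size_xy=0.08, z_step=0.25) -> ChannelStack:
    return ChannelStack(
        green=np.asarray(green, dtype=float),
        red=np.asarray(red, dtype=float),
        pixel_size_xy=pixel_size_xy,
        z_step=z_step,
    )
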