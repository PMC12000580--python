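import numpy as np
import pytest

from uexmtools import profilekit as pk
from uexmtools import synthgen as sg


@pytest.fixture
def noiseless_model():
    """Unexpanded, unblurred, noise-free rendering: geometry passes through."""
    return sg.ImagingModel(
        pixel_size_nm=10.0,
        psf_sigma_nm=0.0,
        background_offset=0.0,
        photon_scale=1.0,
        read_noise_sd=0.0,
        expansion_factor=1.0,
        shot_noise=False,
    )


@pytest.fixture
def cal4():
    """A 4x expansion calibration (16 mm disk from the 4 mm punch)."""
    return pk.calibrate_expansion(16.0)


def make_profile(values, step_nm=1.0, channel="ch"):
    values = np.asarray(values, dtype=float)
    return pk.LineProfile(np.arange(values.size) * step_nm, {channel: values}, step_nm)
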