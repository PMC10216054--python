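import numpy as np
import pytest

from shapeifp import ROISpec
from shapeifp.synthetic import SyntheticTruth, gen_rf_frameset

F0 = 8.5e6
FS = 62.5e6


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def roi():
    return ROISpec(4, 12, 128, 384)


@pytest.fixture
def tone_components():
    """Programmed tones: subharmonic 30 dB, fundamental, ultra-, 2nd harmonic."""
    return [(F0 / 2, 30.0), (F0, 55.0), (1.5 * F0, 25.0), (2 * F0, 40.0)]


@pytest.fixture
def tone_frameset(roi, tone_components):
    """Jitter-free frame set with exactly known tone amplitudes in the ROI."""
    truth = SyntheticTruth(-0.15, 40.0, 0.0, seed=7)
    return gen_rf_frameset(
        truth, roi, fs=FS, f0=F0,
        components=tone_components, sigma_frame_db=0.0,
    )
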