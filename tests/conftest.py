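import numpy as np
import pytest

from spheroidquant.calibration import PixelCalibration


@pytest.fixture
def cal():
    """1 µm/px in-plane, 10 µm z-steps — the central-slice geometry."""
    return PixelCalibration(xy_size=1.0, z_step=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
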