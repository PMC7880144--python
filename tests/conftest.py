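import numpy as np
import pytest

from ocuload.io import CameraGeometry, GazeRecording


@pytest.fixture
def camera() -> CameraGeometry:
    """Wearable-tracker scene camera: 1920x1080 px, 160 deg horizontal FOV."""
    return CameraGeometry()


def make_recording(t, x, y=None, valid=None, rate=100.0) -> GazeRecording:
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.zeros_like(x) if y is None else np.asarray(y, float)
    return GazeRecording.from_arrays(t, x, y, valid=valid, nominal_rate=rate)


@pytest.fixture
def stationary_recording() -> GazeRecording:
    """2 s of perfectly stationary gaze at 100 Hz."""
    t = np.arange(200) / 100.0
    return make_recording(t, np.full(200, 3.0), np.full(200, -1.0))
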