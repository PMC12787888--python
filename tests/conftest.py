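import math

import numpy as np
import pytest

from cehd.camera import CameraModel, DepthFrame


@pytest.fixture
def cam45() -> CameraModel:
    """Default field geometry: 1.8 m mount, 45 deg pitch, mm depth."""
    return CameraModel(fx=400.0, fy=400.0, cx=320.0, cy=240.0)


@pytest.fixture
def cam_level() -> CameraModel:
    """Level camera (pitch 0): depth equals horizontal range."""
    return CameraModel(
        fx=400.0, fy=400.0, cx=320.0, cy=240.0, pitch=0.0, mount_height=1.8
    )


@pytest.fixture
def make_depth():
    """Constant-depth frame builder: make_depth(value_mm, shape)."""

    def _make(value_mm: float, shape=(480, 640)) -> DepthFrame:
        return DepthFrame(np.full(shape, value_mm, dtype=np.uint16))

    return _make
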