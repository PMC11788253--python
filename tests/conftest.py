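import numpy as np
import pytest

from trfd import (
    REFERENCE_CALIBRATION,
    REFERENCE_RESPONSE_FUNCTION,
    Grid2D,
    MachineModel,
    ResponseFunction,
    ScalarMap,
)


@pytest.fixture
def ref_cal():
    """OD-to-dose calibration of the EBT-XD / red-channel readout."""
    return REFERENCE_CALIBRATION


@pytest.fixture
def ref_rf():
    """Film response kernel of the 240 fps readout (60 s support)."""
    return REFERENCE_RESPONSE_FUNCTION


@pytest.fixture
def short_rf():
    """Same kernel shape with a 10 s support for fast end-to-end tests."""
    r = REFERENCE_RESPONSE_FUNCTION
    return ResponseFunction(r.offset, r.a_shift, r.c_slope, duration_s=10.0)


@pytest.fixture
def machine():
    return MachineModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_map(sigma_mm=3.8, peak=5.0, pitch=0.14, half_mm=15.0,
                 center=(0.0, 0.0)) -> ScalarMap:
    g = Grid2D.centered(half_mm, pitch)
    xx, yy = np.meshgrid(g.x_centers(), g.y_centers())
    vals = peak * np.exp(
        -((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * sigma_mm**2)
    )
    return ScalarMap(vals, pitch, g.origin_mm)
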