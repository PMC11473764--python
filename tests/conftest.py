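import numpy as np
import pytest

from hoct.calibration import CalibrationCurve
from hoct.volumes import CTVolume, VoxelGrid


@pytest.fixture
def reference_curve() -> CalibrationCurve:
    """Soft-tissue calibration line HU = 26.36 + 29.89 c."""
    return CalibrationCurve(intercept_m=26.36, slope_b=29.89)


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid((1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (10, 10, 10))


def make_volume(grid: VoxelGrid, values, **kw) -> CTVolume:
    arr = np.broadcast_to(np.asarray(values, dtype=float), grid.shape).copy()
    return CTVolume(grid, arr, **kw)
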