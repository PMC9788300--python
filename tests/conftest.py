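import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from repsecr import (
    CaptureData,
    DetectionParams,
    Detector,
    DetectorArray,
    HabitatMask,
)


@pytest.fixture(scope="session")
def toy_array():
    """Two detectors 1 km apart, two occasions."""
    return DetectorArray(
        array_id="toy",
        detectors=(Detector("d1", 0.0, 0.0), Detector("d2", 1000.0, 0.0)),
        n_occasions=2,
    )


@pytest.fixture(scope="session")
def toy_mask():
    """A 5 x 5 grid of 500-m cells centred between the toy detectors."""
    side = 500.0
    gx = 500.0 + (np.arange(5) - 2) * side
    gy = (np.arange(5) - 2) * side
    xx, yy = np.meshgrid(gx, gy)
    return HabitatMask(
        cell_centers=np.column_stack([xx.ravel(), yy.ravel()]),
        cell_area=(side / 1000.0) ** 2,
        buffer_m=1000.0,
    )


@pytest.fixture(scope="session")
def toy_params():
    return DetectionParams(g0=0.3, sigma=800.0)


@pytest.fixture(scope="session")
def toy_captures(toy_array):
    """Three animals with hand-written histories on the toy array."""
    omega = np.zeros((3, 2, 2), dtype=np.int8)
    omega[0, 0, 0] = 1
    omega[0, 1, 1] = 1  # animal 1: both detectors
    omega[1, 0, 1] = 1  # animal 2: single detection
    omega[2, 0, 0] = 1
    omega[2, 1, 0] = 1  # animal 3: same detector twice
    return CaptureData(array_id="toy", individuals=("a", "b", "c"), omega=omega)
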