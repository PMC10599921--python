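import numpy as np
import pytest

from tspoquant.cohort import BloodTruth, _default_region_truth
from tspoquant.frames import make_frame_schedule

BASE_2TCM = (0.10, 0.05, 0.03, 0.03)  # K1 ml/cm3/min, k2..k4 1/min; VT = 4.0


@pytest.fixture(scope="session")
def schedule():
    """The 26-frame / 90-min dynamic schedule."""
    return make_frame_schedule()


@pytest.fixture(scope="session")
def blood_truth():
    return BloodTruth()


@pytest.fixture(scope="session")
def true_input(blood_truth):
    """Ground-truth arterial input sampled on a 1-s grid, no delay."""
    return blood_truth.to_input()


@pytest.fixture(scope="session")
def region_truth():
    return _default_region_truth()


@pytest.fixture(scope="session")
def noiseless_tac(true_input, schedule):
    from tspoquant.kinetics import twotcm_predict

    return twotcm_predict(BASE_2TCM, true_input, schedule)
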