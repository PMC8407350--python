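import numpy as np
import pytest

from nitromet.build import build_core_model
from nitromet.calibration import RatePair, calibrate
from nitromet.fba import atp_yield

#: published chemostat operating line: uptake = slope*mu + intercept
PUBLISHED_INTERCEPT = 0.90
PUBLISHED_OPERATING_POINT = (8.5, 0.006)
PUBLISHED_SLOPE = (
    PUBLISHED_OPERATING_POINT[0] - PUBLISHED_INTERCEPT
) / PUBLISHED_OPERATING_POINT[1]


@pytest.fixture(scope="session")
def model():
    """Default core model (uncalibrated nominal maintenance)."""
    return build_core_model()


@pytest.fixture(scope="session")
def nitrite_yield(model):
    return atp_yield(model, "nitrite")


@pytest.fixture(scope="session")
def line_pairs():
    """Noise-free chemostat pairs on the published maintenance line."""
    return [
        RatePair(PUBLISHED_SLOPE * mu + PUBLISHED_INTERCEPT, mu)
        for mu in (0.002, 0.004, 0.006, 0.008, 0.010, 0.012)
    ]


@pytest.fixture(scope="session")
def calibrated(model, line_pairs, nitrite_yield):
    """(calibrated model, CalibrationResult) for the published line."""
    return calibrate(model, line_pairs, nitrite_yield, PUBLISHED_OPERATING_POINT)


@pytest.fixture(scope="session")
def calibrated_model(calibrated):
    return calibrated[0]
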