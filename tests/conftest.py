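import numpy as np
import pytest

from discmech.acquisition import default_protocol
from discmech.biomech import Geometry, RampSchedule
from discmech.synthetic import TissueGroundTruth, tensor_from_md_fa


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def np_truth():
    """Nucleus pulposus in-situ ground truth (study group means)."""
    return TissueGroundTruth(t1=1140.0, t2=124.0, mtr=0.34,
                             tensor=tensor_from_md_fa(15.04e-4, 0.0803),
                             s0=1000.0)


@pytest.fixture(scope="session")
def geometry():
    """5 mm diameter, 1.6 mm thick punch."""
    return Geometry(radius_mm=2.5, thickness_mm=1.6)


@pytest.fixture(scope="session")
def short_confined_schedule():
    return RampSchedule(n_ramps=2, strain_increment=0.05,
                        ramp_duration=60.0, hold_duration=900.0)
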