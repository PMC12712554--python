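import numpy as np
import pytest

from saccatt import FieldGeometry, ParameterSet
from saccatt.experiment import FP, ST
from saccatt.signals import make_eye_trajectory


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def geometry() -> FieldGeometry:
    return FieldGeometry()


@pytest.fixture(scope="session")
def trajectory(geometry, params):
    return make_eye_trajectory(FP, ST, params.saccade_onset, geometry, params)
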