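import math

import numpy as np
import pytest

from resusbench import (
    OutflowConfig,
    design_vessel_from_curve,
    crystalloid_curve,
    whole_blood_curve,
)
from resusbench.vessel import MM_H2O_PER_MMHG


@pytest.fixture(scope="session")
def wb_profile():
    """Whole-blood vessel: right cylinder, r = 27 mm."""
    return design_vessel_from_curve(whole_blood_curve())


@pytest.fixture(scope="session")
def crys_profile():
    """Crystalloid vessel: funnel from the default parabolic curve."""
    return design_vessel_from_curve(crystalloid_curve())


@pytest.fixture(scope="session")
def outflow_cfg():
    return OutflowConfig()


@pytest.fixture(scope="session")
def cylinder_ml_per_mmhg():
    """Closed-form compliance of the r=27 mm cylinder, mL per mmHg."""
    return math.pi * 27.0**2 * MM_H2O_PER_MMHG / 1000.0


@pytest.fixture
def rng():
    return np.random.default_rng(42)
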