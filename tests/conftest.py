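import math

import pytest

from railfall import Anthropometry, RailingScenario

# The worked case: a small person (1.58 m, 65 kg) leaning over a 0.92 m
# railing, homogeneous rod (a = b = 0.5).
CASE_LENGTH = 1.58
CASE_MASS = 65.0
CASE_RAILING = 0.92


@pytest.fixture
def case_anthro() -> Anthropometry:
    return Anthropometry(total_length=CASE_LENGTH, mass=CASE_MASS)


@pytest.fixture
def scenario_low_friction() -> RailingScenario:
    """Smooth/wet contact: mu = 0.2."""
    return RailingScenario(railing_height=CASE_RAILING, friction_coefficient=0.2)


@pytest.fixture
def scenario_high_friction() -> RailingScenario:
    """Typical concrete-shoe contact: mu = 0.7."""
    return RailingScenario(railing_height=CASE_RAILING, friction_coefficient=0.7)


@pytest.fixture
def alpha_10() -> float:
    return math.radians(10.0)
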