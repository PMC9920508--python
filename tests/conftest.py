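import numpy as np
import pytest

from pttbp.bp_model import SubjectProfile
from pttbp.synthetic_data import ScenarioSpec, generate_record


@pytest.fixture(scope="session")
def subject() -> SubjectProfile:
    """Reference subject: 1.70 m, default blood density and correction."""
    return SubjectProfile(height=1.70)


@pytest.fixture(scope="session")
def clean_scenario() -> ScenarioSpec:
    """20 s clean record at the default operating point (HR 60, 1 kHz)."""
    return ScenarioSpec(duration=20.0, random_seed=11)


@pytest.fixture(scope="session")
def clean_record(clean_scenario, subject):
    return generate_record(clean_scenario, subject)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230203)
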