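import numpy as np
import pytest

from dfu_heor import (
    HealthState,
    ModelConfig,
    TransitionParameters,
    base_case_economics,
    placeholder_transition_parameters,
    validate_transitions,
)
from dfu_heor.feasibility import load_reference_cohort

S = HealthState


@pytest.fixture(scope="session")
def placeholder_params():
    return placeholder_transition_parameters()


@pytest.fixture()
def econ():
    return base_case_economics("monthly")


@pytest.fixture(scope="session")
def cohort():
    return load_reference_cohort()


@pytest.fixture()
def short_config():
    """Ten-year horizon for tests that do not need the lifetime run."""
    return ModelConfig(max_age_years=77.0)


def identity_params() -> TransitionParameters:
    """All outflows explicitly zero, including the amputation tunnel."""
    outflows = {
        (s, t): 0.0
        for s in S
        for t in S
        if s != t and bool(np.any(placeholder_transition_parameters().mask[s, t]))
    }
    return validate_transitions(TransitionParameters.from_outflows(outflows))
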