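import pytest

from nsmfem.pipeline import estimate_muscle_forces
from nsmfem.synthetic import generate_gait_trial, generic_body_fixture


@pytest.fixture(scope="session")
def body_model():
    return generic_body_fixture()


@pytest.fixture(scope="session")
def xslow_trial(body_model):
    return generate_gait_trial("X-slow", model=body_model)


@pytest.fixture(scope="session")
def xslow_profiles(body_model, xslow_trial):
    return estimate_muscle_forces(body_model, xslow_trial)
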