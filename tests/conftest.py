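import numpy as np
import pytest
from hypothesis import settings

from avhsim.environment import EnvironmentScript
from avhsim.model import GenerativeModel, Observation, Policy

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def single_policy_model():
    """T=2 model with one always-listen policy (smallest nontrivial case)."""
    return GenerativeModel(
        n_steps=2, zeta=0.7, policy_catalog=[Policy.from_string("L")]
    )


@pytest.fixture
def default_model():
    return GenerativeModel()


@pytest.fixture
def alternating_script():
    return EnvironmentScript()


def obs(auditory="silence", proprio="none"):
    return Observation(auditory, proprio)


@pytest.fixture
def make_obs():
    return obs


def assert_distribution(q, atol=1e-10):
    q = np.asarray(q)
    assert (q >= -atol).all()
    np.testing.assert_allclose(q.sum(axis=-1), 1.0, atol=atol)
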