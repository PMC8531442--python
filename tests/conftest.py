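import numpy as np
import pytest

from shoulderelbow import generate_generic_model
from shoulderelbow.synthetic_model import GeneratorParams
from shoulderelbow import kinematics as K
from shoulderelbow import dynamics as D


@pytest.fixture(scope="session")
def model():
    """Default synthetic generic model (male, 1.86 m, 85.5 kg)."""
    return generate_generic_model(GeneratorParams())


@pytest.fixture(scope="session")
def model_hand(model):
    """Generic model with the hand folded into the radius."""
    return D.add_hand_inertia(model)


@pytest.fixture(scope="session")
def abduction_traj(model):
    """Medium-resolution scapular-plane abduction used across tests."""
    return K.abduction_trajectory(20.0, 150.0, 14, 2.0, model)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
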