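import pytest

from fuzzyfes.flc import default_flc_config
from fuzzyfes.plant import PlantParams, default_plant_params


@pytest.fixture(scope="session")
def flc_config():
    return default_flc_config()


@pytest.fixture(scope="session")
def plant_params():
    return default_plant_params()


@pytest.fixture(scope="session")
def pendulum_params():
    """Gravity-dominated, overdamped parameter set with no elastic moment.

    Overdamping keeps a small release monotone, so the 0-degree hard stop
    never engages and the linearized closed form applies throughout.
    """
    return PlantParams(inertia=0.05, gravity_moment=1.7, damping=0.8,
                       stiffness=0.0, rest_angle_deg=0.0,
                       torque_gain=0.005, activation_tau=0.2)
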