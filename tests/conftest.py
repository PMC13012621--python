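import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from fclsim.brownian_engine import SimulationConfig
from fclsim.model_core import DEFAULT_GEOMETRY, RigidMolecule
from fclsim.reaction_kinetics import RateTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def membrane_clathrin():
    """A clathrin in the membrane-bound pose (leg plane parallel to z = 0)."""
    return RigidMolecule(
        id=0, species="clathrin", position=np.array([500.0, 500.0, 2.0])
    )


@pytest.fixture
def tiny_config():
    """A very small, fast configuration for engine unit tests."""
    return SimulationConfig(
        box_edge=300.0,
        n_clathrin=12,
        n_ap2=8,
        duration=300.0,
        frame_interval=30.0,
        rates=RateTable(
            k_cc_gated=4565.0,
            k_ap2_clat=2000.0,
            koff_cc=100.0,
            koff_ap2_clat=1.0,
        ),
        seed=7,
    )


@pytest.fixture
def pure_diffusion_config():
    """All rates zero: the engine reduces to rigid-body Brownian motion."""
    return SimulationConfig(
        box_edge=300.0,
        n_clathrin=10,
        n_ap2=0,
        duration=300.0,
        frame_interval=30.0,
        rates=RateTable(
            k_cc_gated=0.0, k_cc_free=0.0, k_ap2_clat=0.0, koff_cc=0.0, koff_ap2_clat=0.0
        ),
        seed=3,
    )
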