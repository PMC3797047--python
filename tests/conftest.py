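import numpy as np
import pytest

from grsvd.dmd import SimulationConfig, SystemState, initial_state
from grsvd.potentials import make_spec


@pytest.fixture(scope="session")
def hs_spec():
    return make_spec("hs")


@pytest.fixture(scope="session")
def sw_spec():
    return make_spec("sw", {"lam": 1.25, "eps": 1.0})


@pytest.fixture(scope="session")
def warm_kernel(hs_spec):
    """Trigger numba compilation once so individual tests time honestly."""
    from grsvd.dmd import Simulation
    config = SimulationConfig(phi=0.1, N=32, seed=0)
    state = initial_state(hs_spec, config)
    Simulation(state, hs_spec).advance(0.5)
    return True


def small_state(spec, phi=0.2, N=32, seed=0):
    config = SimulationConfig(phi=phi, N=N, seed=seed)
    return initial_state(spec, config), config


@pytest.fixture
def two_particle_state():
    """Head-on pair: gap 2 sigma, closing speed 1 -> core contact at t = 2."""
    L = 10.0
    pos = np.array([[3.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
    vel = np.array([[0.5, 0.0, 0.0], [-0.5, 0.0, 0.0]])
    return SystemState(2, L, pos, vel)
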