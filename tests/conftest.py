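import numpy as np
import pytest

from pulsecr import Parameters, SeasonState
from pulsecr.equilibrium import find_attractor
from pulsecr.life_history import coupled_environment

# deterministic hypothesis profile (the package itself is randomless; this
# keeps the property tests reproducible too)
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults():
    """Factory for the standard parameterisation with chosen theta, mu."""

    def make(theta: float, mu: float, **kw) -> Parameters:
        return Parameters(theta=theta, mu=mu, **kw)

    return make


HIGH_IC = SeasonState(1.0, 0.2, 0.2, 0.0)
LOW_IC = SeasonState(1.0, 0.01, 0.01, 0.0)


@pytest.fixture(scope="session")
def lh_params():
    """The parameter set used throughout the life-history analyses."""
    return Parameters(theta=1.0, mu=8.0)


@pytest.fixture(scope="session")
def lh_attractor(lh_params):
    """Coexistence attractor at theta=1, mu=8 (shared across tests)."""
    return find_attractor(lh_params, HIGH_IC)


@pytest.fixture(scope="session")
def lh_coupled_env(lh_params):
    """Frozen fixed-point-season resource trajectory at theta=1, mu=8."""
    return coupled_environment(lh_params)
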