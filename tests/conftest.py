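import numpy as np
import pytest

from sympatry.landscape import EcoParams, Landscape
from sympatry.foraging import ForagingState


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def eco():
    return EcoParams()


def make_state(
    width=8,
    height=8,
    positions=((2, 2),),
    alpha=0.5,
    delta=1.0,
    rho=1.0,
    biomass=1.0,
    params=None,
    initial=None,
):
    """Small foraging world with identical-strategy agents at given positions."""
    params = params or EcoParams()
    landscape = Landscape(width, height, params=params, initial=initial)
    n = len(positions)
    return ForagingState(
        landscape=landscape,
        pos=np.array(positions),
        biomass=np.full(n, float(biomass)),
        alpha=np.full(n, float(alpha)),
        delta=np.full(n, float(delta)),
        rho=np.full(n, float(rho)),
    )


@pytest.fixture
def state_factory():
    return make_state
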