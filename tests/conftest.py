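import numpy as np
import pytest

from cleftsim import ModelParams
from cleftsim.model import SimulationState


@pytest.fixture
def small_params():
    """A small lattice that still has a cleft, a spheroid and bulk volume."""
    return ModelParams(nx=21, ny=21, nz=11, spheroid_radius=30.0, n_steps=20)


@pytest.fixture
def random_state():
    """Factory for random bounded states on a small lattice."""

    def make(params: ModelParams, seed: int = 0) -> SimulationState:
        rng = np.random.default_rng(seed)
        shape = (params.nx, params.ny, params.nz)
        return SimulationState(
            cells=rng.random(shape),
            ecm=rng.random(shape),
            step=0,
        )

    return make
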