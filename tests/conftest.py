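import numpy as np
import pytest

from acdsim import geometry as geo
from acdsim.model_core import UPRC, PopulationPhaseState, SystemState


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def focal_geometry():
    """A reproducible 3-contact / 3-population system with eta ~ 0.1."""
    return geo.generate_system(0.1, L=3, S=3, seed=7)


def random_system_state(rng, S=3, N=40, clustered=True):
    """Random multi-population state; clustered states concentrate each
    population around its own mean phase so local amplitudes are large."""
    pops = []
    sizes = rng.integers(10, N + 1, size=S)
    total = sizes.sum()
    for s in range(S):
        centre = rng.uniform(0, 2 * np.pi)
        spread = rng.uniform(0.2, 1.2) if clustered else 2 * np.pi
        theta = centre + spread * rng.standard_normal(sizes[s])
        pops.append(
            PopulationPhaseState(
                theta=np.mod(theta, 2 * np.pi),
                omega=rng.standard_normal(sizes[s]),
                weight=sizes[s] / total,
            )
        )
    return SystemState(pops, t=0.0)


@pytest.fixture
def sinus_uprc():
    return UPRC.sinusoidal(2.0)
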