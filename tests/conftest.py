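import numpy as np
import pytest

from qsdyn.engine import RunConfig
from qsdyn.environment import GridSpec
from qsdyn.lsr_model import LsrParams
from qsdyn.luxir_model import LuxParams
from qsdyn.population import GrowthSpec, HeterogeneitySpec


@pytest.fixture(scope="session")
def lsr_params():
    return LsrParams()


@pytest.fixture(scope="session")
def lux_params():
    return LuxParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """A 40 x 40 um grid with slow diffusion (cheap FTCS)."""
    return GridSpec(Lx=40.0, Ly=40.0, dx=4.0, dt_engine=1.0, D=2.0)


@pytest.fixture
def quick_lsr_config():
    """A very small, fast Lsr swim run for engine plumbing tests."""
    return RunConfig(
        model="lsr",
        motility="swim",
        grid=GridSpec(Lx=60.0, Ly=60.0, dx=4.0, dt_engine=2.0, D=2.0),
        heterogeneity=HeterogeneitySpec(
            target="basal", median=487.8, sigma=0.0125, log_base="e", seed=7
        ),
        growth=GrowthSpec(),
        n_initial=12,
        t_end=30.0,
        seed=7,
    )
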