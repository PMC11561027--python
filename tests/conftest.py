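import numpy as np
import pytest

from avtumor import experiments, radial
from avtumor.fields import ModelParams
from avtumor.grid import build_lattice


@pytest.fixture(scope="session")
def fine_grid():
    """h = 0.01 unit-disc lattice (expensive to factorize; shared)."""
    return build_lattice(0.01, 1.0)


@pytest.fixture(scope="session")
def medium_grid():
    return build_lattice(0.02, 1.0)


@pytest.fixture(scope="session")
def coarse_grid():
    return build_lattice(0.04, 1.0)


@pytest.fixture(scope="session")
def pde_params() -> ModelParams:
    return experiments.preset("table2_pde")


@pytest.fixture(scope="session")
def dlcm_params() -> ModelParams:
    return experiments.preset("table2_dlcm")


@pytest.fixture(scope="session")
def stationary_state(pde_params):
    """Equilibrium zonation under the standard mean-field parameters."""
    return radial.find_stationary(pde_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240517)
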