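import numpy as np
import pytest

from abcmk import SelectionModel, solve_scenario


@pytest.fixture(scope="session")
def equilibrium_model() -> SelectionModel:
    """The demographic-equilibrium baseline: N = n = 500, Gamma DFE
    (shape 0.184, mean |2Ns| = 457), beneficial classes 2Ns = 10 / 500."""
    return SelectionModel(N=500, n=500)


@pytest.fixture(scope="session")
def solved_04_01(equilibrium_model):
    """Scenario solved for alpha = 0.4, alpha_W = 0.1 at negligible BGS."""
    return solve_scenario(0.4, 0.1, equilibrium_model.with_B(0.999))


@pytest.fixture(scope="session")
def small_model() -> SelectionModel:
    """A small population for cheap brute-force cross-checks."""
    return SelectionModel(N=50, n=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
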