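import numpy as np
import pytest

from plasmodesim import get_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario_p2():
    return get_scenario("p2n100rho0.2")


@pytest.fixture(scope="session")
def oracle_p2():
    """Conditional-variance true-MSE oracle for the p=2, n=100, rho=0.2
    scenario, shared across tests."""
    from plasmodesim import true_mse

    sc = get_scenario("p2n100rho0.2")
    return true_mse(sc.dgp, sc.ogm, sc.n, 100_000, np.random.default_rng(777))
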