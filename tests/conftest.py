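import numpy as np
import pytest

from carliu.simulation import build_beta, gen_design, gen_response
from carliu.weights import lattice_weights


@pytest.fixture(scope="session")
def queen7():
    return lattice_weights(7, "queen")


@pytest.fixture(scope="session")
def rook3():
    return lattice_weights(3, "rook")


@pytest.fixture
def rng():
    return np.random.default_rng(20230404)


@pytest.fixture(scope="session")
def sim_dataset(queen7):
    """Factory for simulated CAR datasets on the 7x7 queen lattice."""

    def make(seed=0, delta=0.0, p1=5, p2=10, rho=0.5, rho_x=0.3, sigma2=1.0):
        r = np.random.default_rng(seed)
        X = gen_design(queen7.n_sites, p1 + p2, rho_x, r)
        beta = build_beta(p1, p2, delta)
        Y = gen_response(X, beta, rho, sigma2, queen7, r)
        return Y, X, beta

    return make
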