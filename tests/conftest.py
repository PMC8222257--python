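import warnings

import numpy as np
import pytest

from pollinet.model import (
    IncidenceMatrix,
    ModelParameters,
    PriorConfig,
    VisitationMatrix,
)


@pytest.fixture(autouse=True)
def _quiet_zero_species_warning():
    # random small matrices routinely contain empty species; keep logs usable
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="visitation matrix contains species with zero"
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260903)


@pytest.fixture
def prior():
    return PriorConfig()


def random_params(rng, n_p, n_a, c_range=(1.0, 50.0), r_range=(0.0, 60.0)):
    return ModelParameters(
        C=float(rng.uniform(*c_range)),
        r=float(rng.uniform(*r_range)),
        rho=float(rng.uniform(0.05, 0.95)),
        sigma=rng.dirichlet(np.ones(n_p)),
        tau=rng.dirichlet(np.ones(n_a)),
    )


@pytest.fixture
def small_data(rng):
    return VisitationMatrix(rng.integers(0, 8, size=(3, 3)))


@pytest.fixture
def small_network(rng):
    return IncidenceMatrix(rng.integers(0, 2, size=(3, 3)))
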