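import numpy as np
import pytest

from cellwalk import CellParameters, load_preset
from cellwalk.parameters import FieldValues


class ConstantFields:
    """Spatially uniform material fields for closed-form checks."""

    def __init__(self, beta, E, tau, sigma_active, mu):
        self.beta = beta
        self.E = E
        self.tau = tau
        self.sigma_active = sigma_active
        self.mu = mu

    def evaluate(self, x, r=None, f=None):
        ones = np.ones(np.shape(x), dtype=float)
        return FieldValues(
            beta=self.beta * ones,
            E=self.E * ones,
            tau=self.tau * ones,
            sigma_active=self.sigma_active,
            mu=self.mu,
        )


@pytest.fixture(scope="session")
def table1() -> CellParameters:
    return load_preset("table1")


@pytest.fixture(scope="session")
def calibrated() -> CellParameters:
    return load_preset("table1_calibrated")


@pytest.fixture
def constant_fields_factory():
    return ConstantFields
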