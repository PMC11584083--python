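import numpy as np
import pytest

import broilergrowth as bg


@pytest.fixture(scope="session")
def table3():
    """The seven observed weekly mean weights (g)."""
    return bg.table3_observed()


@pytest.fixture(scope="session")
def table1():
    """Reported growth-model parameters, keyed by family."""
    return bg.table1_parameters()


@pytest.fixture(scope="session")
def printed_mars():
    """The reported hinge-spline model for weight vs age."""
    return bg.printed_mars_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
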