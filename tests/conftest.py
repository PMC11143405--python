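import numpy as np
import pytest

from ollged import (
    Exponential,
    GeneralizedExponential,
    LogLogistic,
    OddLogLogisticGE,
    load_builtin,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


#: parameter triples used repeatedly across tests (lambda, alpha, gamma)
PARAM_GRID = [
    (0.2, 0.2, 0.2),
    (0.5, 1.0, 2.0),
    (1.0, 1.0, 1.0),
    (1.0, 2.0, 2.0),
    (1.5, 1.5, 0.8),
    (2.0, 0.5, 1.5),
    (5.0, 5.0, 5.0),
]


@pytest.fixture(scope="session")
def kiama():
    return load_builtin("kiama64")


@pytest.fixture(scope="session")
def chemo():
    return load_builtin("chemo45")


@pytest.fixture(scope="session")
def ollged_kiama(kiama):
    return OddLogLogisticGE(kiama.values).fit(seed=1)


@pytest.fixture(scope="session")
def ollged_chemo(chemo):
    return OddLogLogisticGE(chemo.values).fit(seed=1)


@pytest.fixture(scope="session")
def ged_kiama(kiama):
    return GeneralizedExponential(kiama.values).fit(seed=1)


@pytest.fixture(scope="session")
def lld_kiama(kiama):
    return LogLogistic(kiama.values).fit(seed=1)


@pytest.fixture(scope="session")
def ed_kiama(kiama):
    return Exponential(kiama.values).fit(seed=1)
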