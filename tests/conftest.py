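import numpy as np
import pytest

from crnt import fixtures as fx
from crnt.deficiency import search_def
from crnt.injectivity import search_inj
from crnt.optimize import SearchOptions


@pytest.fixture(scope="session")
def motif():
    return fx.fixture("motif_closed")


@pytest.fixture(scope="session")
def motif_sd():
    return fx.fixture("motif_semidiffusive")


@pytest.fixture(scope="session")
def example_open():
    return fx.fixture("example_open")


@pytest.fixture(scope="session")
def example_closed():
    return fx.fixture("example_closed")


@pytest.fixture(scope="session")
def motif_certificate(motif):
    """A certified saddle-node of the closed motif (deficiency route)."""
    res = search_def(motif, options=SearchOptions(seed=1, multistarts=10))
    assert res.found
    return res.certificate


@pytest.fixture(scope="session")
def motif_sd_certificate(motif_sd):
    """A certified saddle-node of the semi-diffusive motif (injectivity route)."""
    res = search_inj(motif_sd, options=SearchOptions(seed=1, multistarts=10))
    assert res.found
    return res.certificate


@pytest.fixture(scope="session")
def stat_certificate():
    """A certified saddle-node of the closed early-STAT module whose branch in
    the receptor total carries a bistable window (used by the coupled tests)."""
    net = fx.fixture("stat_early_closed")
    res = search_def(net, options=SearchOptions(seed=3, multistarts=10))
    assert res.found
    return res.certificate


def random_positive(rng, n, decades=2.0):
    return 10.0 ** rng.uniform(-decades, decades, n)
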