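import numpy as np
import pytest

from conserved_moieties import (
    build_atn,
    das_fixture,
    dopa_decarboxylase_fixture,
    identify_moieties,
    split_matrices,
)


@pytest.fixture(scope="session")
def das():
    return das_fixture("a")


@pytest.fixture(scope="session")
def das_d():
    return das_fixture("d")


@pytest.fixture(scope="session")
def dopa():
    return dopa_decarboxylase_fixture()


@pytest.fixture(scope="session")
def das_N(das):
    N, _ = split_matrices(das.network)
    return N


@pytest.fixture(scope="session")
def das_atn(das):
    return build_atn(das.network, das.mappings)


@pytest.fixture(scope="session")
def das_moieties(das_atn):
    return identify_moieties(das_atn)


@pytest.fixture(scope="session")
def table4(das):
    """The seven reference moiety vectors, keyed l1..l7."""
    return {k: np.array(v) for k, v in das.expected["moiety_vectors"].items()}


def column_set(L) -> set[tuple]:
    L = np.asarray(L)
    return {tuple(L[:, k]) for k in range(L.shape[1])}
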