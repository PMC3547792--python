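import pytest

from fluxredirect import (
    ToyNetworkSpec,
    build_flat_library,
    derive_enzyme_groups,
    make_toy_network,
)


@pytest.fixture(scope="session")
def t1():
    return make_toy_network(ToyNetworkSpec("T1"))


@pytest.fixture(scope="session")
def t2():
    return make_toy_network(ToyNetworkSpec("T2", chain_length=5))


@pytest.fixture(scope="session")
def t3():
    return make_toy_network(ToyNetworkSpec("T3"))


@pytest.fixture(scope="session")
def t4():
    return make_toy_network(ToyNetworkSpec("T4"))


@pytest.fixture(scope="session")
def t1_lib(t1):
    return build_flat_library(derive_enzyme_groups(t1))


@pytest.fixture(scope="session")
def t2_lib(t2):
    return build_flat_library(derive_enzyme_groups(t2))


@pytest.fixture(scope="session")
def t4_lib(t4):
    return build_flat_library(derive_enzyme_groups(t4))
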