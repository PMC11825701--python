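import pytest

from isoforge.simulate import (
    SimConfig,
    make_erbb2_like_fixture,
    make_reference,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def erbb2():
    return make_erbb2_like_fixture()


@pytest.fixture(scope="session")
def small_reference():
    return make_reference(SimConfig(seed=7, n_genes=6))


@pytest.fixture(scope="session")
def small_index(small_reference):
    return small_reference.index


@pytest.fixture(scope="session")
def dataset():
    return simulate_dataset(SimConfig(seed=11, n_genes=10, samples=5))
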