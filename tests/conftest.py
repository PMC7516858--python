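import numpy as np
import pytest

from confirmlab import ContingencyTable, TestProfile


@pytest.fixture
def nat_profile() -> TestProfile:
    """Low-sensitivity, high-specificity assay (nucleic-acid test)."""
    return TestProfile(sensitivity=0.5, specificity=0.95, prior=0.25)


@pytest.fixture
def ct_profile() -> TestProfile:
    """Higher-sensitivity, lower-specificity imaging test (chest CT)."""
    return TestProfile(sensitivity=0.8, specificity=0.75, prior=0.25)


@pytest.fixture
def raven_base() -> ContingencyTable:
    return ContingencyTable(20, 10, 10, 20)


def make_random_tables(count, seed, low=0.01, high=50.0):
    """Strictly positive random count tables (all conditionals defined)."""
    rng = np.random.default_rng(seed)
    return [
        ContingencyTable(*rng.uniform(low, high, size=4)) for _ in range(count)
    ]


@pytest.fixture
def random_positive_tables():
    return make_random_tables(200, seed=1234)
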