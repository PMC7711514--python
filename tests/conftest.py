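import numpy as np
import pytest

from entroprod import catalogue, markov


@pytest.fixture
def two_state_W():
    """Asymmetric two-state chain, rates alpha=2 (1->2), beta=1 (2->1)."""
    return catalogue.two_state_rate_matrix(catalogue.TwoStateSpec(2.0, 1.0, 1.0))


@pytest.fixture
def cyclic3_W():
    """Driven three-state cycle, clockwise 2, counter-clockwise 1."""
    return catalogue.cyclic_rate_matrix(3, 2.0, 1.0)


@pytest.fixture
def random_W4():
    return markov.random_rate_matrix(4, seed=42, mode="generic")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_probability(rng, d):
    p = rng.dirichlet(np.ones(d))
    return p / p.sum()
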