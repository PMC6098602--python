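import numpy as np
import pytest

from trild import HaplotypeFrequencies, haplotypes_to_params


def make_random_haplotypes(rng, alpha: float = 1.0) -> HaplotypeFrequencies:
    """Random point on the 8-simplex (Dirichlet); always a valid tensor."""
    return HaplotypeFrequencies(rng.dirichlet(np.full(8, alpha)).reshape(2, 2, 2))


def make_random_decomposition(rng, alpha: float = 1.0):
    """Random valid decomposition obtained by decomposing a random tensor."""
    return haplotypes_to_params(make_random_haplotypes(rng, alpha))


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def random_haplotypes():
    return make_random_haplotypes


@pytest.fixture
def random_decomposition():
    return make_random_decomposition
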