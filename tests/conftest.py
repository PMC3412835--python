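import numpy as np
import pytest

from mitoarch.datasets import challia_fletcheri_genome
from mitoarch.rearrange import ancestral_insect_order, order_from_genome


@pytest.fixture(scope="session")
def cf_genome():
    """The published C. fletcheri annotation (coordinates only)."""
    return challia_fletcheri_genome()


@pytest.fixture(scope="session")
def cf_order(cf_genome):
    return order_from_genome(cf_genome)


@pytest.fixture(scope="session")
def ancestral():
    return ancestral_insect_order()


@pytest.fixture
def rng():
    return np.random.default_rng(20456)


def random_dna(rng, n, probs=(0.25, 0.25, 0.25, 0.25)):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=n, p=list(probs)).tobytes().decode()
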