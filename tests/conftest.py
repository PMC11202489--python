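import numpy as np
import pytest

from shellnet.design import make_design


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def small_genome_run():
    """A small seeded genome + reads fixture shared by junction tests."""
    from shellnet.synthetic import simulate_genome_and_reads
    return simulate_genome_and_reads(n_genes=8, n_circ=5, read_length=100,
                                     junction_depth=3, n_linear=200, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
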