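import numpy as np
import pytest

from squigsim.fixtures import FixtureSpec, synth_genome, synth_pore_table
from squigsim.pore_model import TablePoreModel


@pytest.fixture(scope="session")
def k3_table():
    """64-row pore table: small enough that failures are human-readable."""
    return synth_pore_table(FixtureSpec(seed=11, k=3))


@pytest.fixture(scope="session")
def k6_table():
    return synth_pore_table(FixtureSpec(seed=11, k=6))


@pytest.fixture(scope="session")
def small_genome():
    """10 kb single-contig circular genome."""
    return synth_genome(FixtureSpec(genome_length=10_000, seed=7), topology="circular")


@pytest.fixture(scope="session")
def linear_genome():
    return synth_genome(FixtureSpec(genome_length=10_000, n_contigs=2, seed=7),
                        topology="linear")


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def k3_model(k3_table):
    return TablePoreModel(k3_table)
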