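import numpy as np
import pytest

from porefix.fs_align import ProteinSearcher, ScoringScheme
from porefix.mockdata import MockGenomeSpec, gen_reference


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def mock_ref():
    """A small 20-gene mock reference shared across correction tests."""
    return gen_reference(MockGenomeSpec(n_genes=20, gene_len_aa=100, intergenic_len=50, seed=7))


@pytest.fixture(scope="session")
def mock_searcher(mock_ref, scheme):
    return ProteinSearcher(mock_ref.proteins, scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
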