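import numpy as np
import pytest

from popgensim.catalog import Contig
from popgensim.demography import constant_size_model
from popgensim.engine import Genealogy
from popgensim.ratemap import RateMap


def make_contig(
    length,
    recombination_rate=0.0,
    mutation_rate=1e-8,
    ploidy=2,
    gene_conversion_fraction=None,
    gene_conversion_length=None,
    non_crossover_only=False,
):
    return Contig(
        species_id="TestSp",
        chromosome_id="1",
        length=length,
        mutation_rate=mutation_rate,
        rate_map=RateMap.uniform(length, recombination_rate),
        gene_conversion_fraction=gene_conversion_fraction,
        gene_conversion_length=gene_conversion_length,
        non_crossover_only=non_crossover_only,
        ploidy=ploidy,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def constant_model():
    return constant_size_model(1e4)


@pytest.fixture
def balanced_genealogy():
    """Fixed 4-sample balanced tree over [0, 100): ((0,1),(2,3))."""
    return Genealogy(
        node_times=[0.0, 0.0, 0.0, 0.0, 1000.0, 2000.0, 3000.0],
        edges_parent=[4, 4, 5, 5, 6, 6],
        edges_child=[0, 1, 2, 3, 4, 5],
        edges_left=[0, 0, 0, 0, 0, 0],
        edges_right=[100, 100, 100, 100, 100, 100],
        samples=[0, 1, 2, 3],
        contig_length=100,
    )


@pytest.fixture
def pair_genealogy():
    """Two samples coalescing at t=1000 over [0, 100)."""
    return Genealogy(
        node_times=[0.0, 0.0, 1000.0],
        edges_parent=[2, 2],
        edges_child=[0, 1],
        edges_left=[0, 0],
        edges_right=[100, 100],
        samples=[0, 1],
        contig_length=100,
    )
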