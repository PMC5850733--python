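import numpy as np
import pytest

from gibbonmsc.gibbon import (GENE_TREE_1, GENE_TREE_7, candidate_trees,
                              species_tree_model, truth_coal_unit_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def noncoding_cu():
    return truth_coal_unit_tree("noncoding")


@pytest.fixture(scope="session")
def coding_cu():
    return truth_coal_unit_tree("coding")


@pytest.fixture(scope="session")
def gibbon_model():
    return species_tree_model("noncoding", outgroup=True)


@pytest.fixture(scope="session")
def cands5():
    return candidate_trees(outgroup=False)


@pytest.fixture(scope="session")
def cands6():
    return candidate_trees(outgroup=True)


@pytest.fixture(scope="session")
def gibbon_true_gene_trees():
    """4,000 true gene-tree topologies (with outgroup) from the
    noncoding gibbon-like distribution; shared across estimator tests."""
    from gibbonmsc.genedist import sample_topology_counts

    cu = truth_coal_unit_tree("noncoding")
    counts = sample_topology_counts(cu, 4000, np.random.default_rng(99),
                                    outgroup="O")
    return [t for t, c in counts.items() for _ in range(c)]
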