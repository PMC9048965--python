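import pytest

from iridograph import (
    Phylogeny,
    enumerate_space,
    iridoid_grammar,
    toy_grammar,
)


@pytest.fixture(scope="session")
def grammar():
    return iridoid_grammar()


@pytest.fixture(scope="session")
def space(grammar):
    """The full iridoid chemical space (enumerated once per session)."""
    return enumerate_space(grammar)


@pytest.fixture(scope="session")
def toy_space():
    """2-carbon, max-state-1, no-unsaturation space: the 2-bit hypercube."""
    return enumerate_space(toy_grammar())


@pytest.fixture()
def three_taxon_tree():
    """Ultrametric: sisters A,B split 0.2 back; C splits at the root, depth 1."""
    return Phylogeny.from_newick("((A:0.2,B:0.2):0.8,C:1.0);")


@pytest.fixture()
def star_tree():
    return Phylogeny.from_newick("(A:1.0,B:1.0,C:1.0,D:1.0);")
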