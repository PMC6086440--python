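import numpy as np
import pytest

from phylotrace import parse_newick
from phylotrace.treeio import TreeTrace
from phylotrace.synthetic import StickyChainConfig, sample_sticky_chain


@pytest.fixture
def balanced_quartets():
    t1 = parse_newick("((A,B),(C,D));")
    t2 = parse_newick("((A,C),(B,D));")
    return t1, t2


@pytest.fixture
def ultrametric_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def sticky_chain_5taxa():
    """Sticky chain over the 105-topology 5-taxon space with a seeded
    Dirichlet(1) stationary law; shared across estimator tests."""
    config = StickyChainConfig(
        taxa=[f"t{i + 1}" for i in range(5)], alpha=0.8, n=20_000, seed=42
    )
    return sample_sticky_chain(config)


def make_trace(newicks, indices=None):
    trees = [parse_newick(s) for s in newicks]
    taxa = frozenset(l.taxon.label for l in trees[0].leaf_node_iter())
    return TreeTrace(trees=trees, taxa=taxa, indices=indices or [])
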