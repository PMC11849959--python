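import io

import numpy as np
import pytest

from phylomix import tree as treemod


def tree_from_newick(text: str, leaf_order=None):
    """Parse + index a strictly binary Newick string."""
    return treemod.index_nodes(
        treemod.read_newick(io.StringIO(text)), leaf_order=leaf_order
    )


@pytest.fixture
def cherry():
    return tree_from_newick("(A,B);")


@pytest.fixture
def quartet():
    return tree_from_newick("((A,B),(C,D));")


@pytest.fixture
def fig_tree():
    """8-leaf topology whose first leaf sits at depth 4 and last at depth 2."""
    return tree_from_newick("((((t1,t2),(t3,t4)),(t5,t6)),(t7,t8));")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
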