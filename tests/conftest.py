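import numpy as np
import pytest

from phylogs.simulate import simulate_yule_tree
from phylogs.tree import bm_covariance, parse_newick


@pytest.fixture
def cherry():
    """Smallest tree: two tips, unit branches."""
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    """Ultrametric 3-tip tree: ((A:1,B:1):1,C:2);"""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree20():
    """A 20-tip Yule tree with its BM covariance."""
    tree = simulate_yule_tree(20, 1.0, seed=101)
    return tree, bm_covariance(tree)


def brute_force_mrca_depths(tree):
    """Quadratic-time oracle for the BM covariance: per-pair root path scan.

    Walks the explicit root-to-tip node paths and sums branch lengths over
    the shared prefix, independent of the production traversal.
    """
    dtree = tree._tree
    paths = {}
    for leaf in dtree.leaf_node_iter():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = list(reversed(path))
    labels = tree.tip_labels
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is not nb:
                    break
                if na.parent_node is not None:
                    shared += na.edge.length
            C[i, j] = shared
    for i, a in enumerate(labels):
        C[i, i] = sum(
            n.edge.length for n in paths[a] if n.parent_node is not None
        )
    return labels, C
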