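import numpy as np
import pytest

import phyloniche as pn


@pytest.fixture
def cherry():
    return pn.read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return pn.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return pn.read_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture(scope="session")
def yule20():
    return pn.simulate_yule_tree(20, 10.0, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def joint_bm_covariance(newick: str):
    """Independent covariance oracle built from dendropy edge paths.

    Under BM the covariance of any two node values equals the summed lengths
    of the edges their root paths share.  Returns (tip_labels, node_keys,
    full covariance over tips+internal nodes) with internal nodes keyed by
    their sorted descendant-tip frozenset.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    nodes = list(tree.preorder_node_iter())
    paths = {}
    keys = []
    for nd in nodes:
        path = []
        v = nd
        while v.parent_node is not None:
            path.append(id(v))
            v = v.parent_node
        paths[id(nd)] = set(path)
        if nd.is_leaf():
            keys.append(nd.taxon.label)
        else:
            keys.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
    lengths = {id(nd): float(nd.edge.length or 0.0) for nd in nodes}
    m = len(nodes)
    V = np.zeros((m, m))
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            shared = paths[id(a)] & paths[id(b)]
            V[i, j] = sum(lengths[e] for e in shared)
    tip_labels = [k for k in keys if isinstance(k, str)]
    return tip_labels, keys, V
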