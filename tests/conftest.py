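import copy

import pytest

from regionbench.simulate import SimConfig, simulate_genus
from regionbench.tree import Tree, TreeNode


@pytest.fixture(scope="session")
def small_genus():
    """A compact synthetic genus shared by read-only tests."""
    cfg = SimConfig(n_species=6, strains_per_species=2, genome_length=4080,
                    n_marker_genes=3, marker_length=300, seed=11)
    return simulate_genus(cfg)


def _add_leaf_everywhere(tree: TreeNode, label: str):
    """All trees obtained by attaching a new leaf to every edge."""
    out = []

    def edges(node, path):
        for i, child in enumerate(node.children):
            yield path + [i]
            yield from edges(child, path + [i])

    for path in edges(tree, []):
        t = copy.deepcopy(tree)
        node = t
        for i in path[:-1]:
            node = node.children[i]
        child = node.children[path[-1]]
        mid = TreeNode(children=[child, TreeNode(label, 1.0)], length=1.0)
        node.children[path[-1]] = mid
        out.append(t)
    return out


def all_unrooted_topologies(labels):
    """Every unrooted binary topology over the given labels (3, 15, 105...)
    as Tree objects; grown by leaf insertion on every edge."""
    base = TreeNode(children=[TreeNode(lab, 1.0) for lab in labels[:3]])
    trees = [base]
    for lab in labels[3:]:
        trees = [t for tree in trees
                 for t in _add_leaf_everywhere(tree, lab)]
    return [Tree(copy.deepcopy(t), rooted=False) for t in trees]


@pytest.fixture(scope="session")
def six_leaf_topologies():
    trees = all_unrooted_topologies(list("ABCDEF"))
    assert len(trees) == 105
    return trees
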