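import itertools
import string

import numpy as np
import pytest

from redphylo.trees import Node, RootedTree


def random_rooted_tree(rng: np.random.Generator, labels, with_lengths=False) -> RootedTree:
    """Random rooted binary topology by sequential leaf attachment."""
    labels = list(labels)
    assert len(labels) >= 2
    root = Node()
    root.add_child(Node(label=labels[0]))
    root.add_child(Node(label=labels[1]))
    for lab in labels[2:]:
        # pick any non-root node; split its parent edge
        nodes = [n for n in RootedTree(root).postorder() if n.parent is not None]
        target = nodes[rng.integers(len(nodes))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(Node(label=lab))
    tree = RootedTree(root)
    if with_lengths:
        for node in tree.postorder():
            if node.parent is not None:
                node.length = float(np.round(rng.uniform(0.01, 2.0), 6))
    return tree


def leaf_names(n: int) -> list[str]:
    alphabet = list(string.ascii_uppercase)
    if n <= 26:
        return alphabet[:n]
    return [f"T{i}" for i in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def taxa():
    from redphylo.datasets import red_algal_taxa

    return red_algal_taxa()


@pytest.fixture
def species_tree_15():
    from redphylo.datasets import RED_ALGAL_TOPOLOGY
    from redphylo.trees import parse_newick

    return parse_newick(RED_ALGAL_TOPOLOGY)
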