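import numpy as np
import pytest

from dtlflux.tree import SpeciesTree


@pytest.fixture
def quartet() -> SpeciesTree:
    """Balanced 4-tip tree with unit branch lengths (depth 2)."""
    return SpeciesTree.from_newick("((A:1,B:1)ab:1,(C:1,D:1)cd:1)root;")


@pytest.fixture
def two_tip() -> SpeciesTree:
    return SpeciesTree.from_newick("(A:1,B:1)root;")


def random_tree(rng: np.random.Generator, n_tips: int) -> SpeciesTree:
    """A random rooted binary tree with exponential branch lengths."""
    from dtlflux.tree import TreeNode

    nodes = [TreeNode(id="r", parent=None, length=0.0, is_tip=True)]
    by_id = {"r": nodes[0]}
    tips = ["r"]
    counter = 0
    while len(tips) < n_tips:
        target = tips[rng.integers(len(tips))]
        node = by_id[target]
        node.is_tip = False
        for _ in range(2):
            counter += 1
            child = TreeNode(id=f"x{counter}", parent=target,
                             length=float(rng.exponential(1.0)), is_tip=True)
            nodes.append(child)
            by_id[child.id] = child
        tips = [n.id for n in nodes if n.is_tip]
    import copy

    return SpeciesTree(copy.deepcopy(nodes))


@pytest.fixture
def random_tree_factory():
    return random_tree
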