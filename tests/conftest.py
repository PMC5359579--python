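import io

import numpy as np
import pytest
from skbio import TreeNode

import phyloecol as pe


def make_star(k: int) -> TreeNode:
    """k-tip star tree with unit branches (tips T1..Tk)."""
    tips = ",".join(f"T{i}:1" for i in range(1, k + 1))
    tree = TreeNode.read(io.StringIO(f"({tips});"), format="newick")
    tree.length = None
    return tree


def make_random_tree(rng, n_tips, prefix="T") -> TreeNode:
    """Random binary tree with exponential branch lengths."""
    nodes = [TreeNode(name=f"{prefix}{i}", length=float(rng.exponential(1.0)))
             for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(children=[a, b], length=float(rng.exponential(1.0)))
        nodes = [n for k_, n in enumerate(nodes) if k_ not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    root.length = None
    return root


@pytest.fixture(scope="session")
def default_dataset():
    """Full synthetic dataset under the default study conditions."""
    spec = pe.SynthSpec(seed=11)
    tree, lineage, metadata, table = pe.generate_dataset(spec)
    return spec, tree, lineage, metadata, table


@pytest.fixture
def tiny_tree():
    """((A:1,B:1):1,C:2); -- total branch length 5."""
    return pe.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star():
    return make_star


@pytest.fixture
def random_tree():
    return make_random_tree
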