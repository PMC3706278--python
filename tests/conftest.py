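import numpy as np
import pytest

from lssmap.coalescent import Genealogy
from lssmap.local_tree import LocalTree, TreeNode


def make_tree(spec, lengths):
    """Build a LocalTree from a nested-tuple topology.

    ``spec`` is a nested tuple of tip ids, e.g. ``((0, 1), (2, (3, 4)))``;
    ``lengths`` maps each node's frozenset of tip ids to its branch length.
    """
    tips = {}

    def build(s):
        if isinstance(s, int):
            node = TreeNode(tip_id=s, label=f"t{s}")
            tips[s] = node
        else:
            node = TreeNode()
            for child in s:
                node.add_child(build(child))
        return node

    root = build(spec)
    tree = LocalTree(root, [tips[i] for i in sorted(tips)], window=(0, 1))
    for node in tree.preorder():
        if node.parent is not None:
            key = frozenset(np.flatnonzero(node.tip_mask))
            node.length = lengths[key]
    tree.compute_depths()
    return tree


def random_coalescent_matrix(rng, n=8, n_cols=6):
    """Random compatible 0/1 matrix: one mutation per column on a random tree.

    Columns are clades of a random Kingman-style topology, so the matrix
    always admits a perfect phylogeny rooted at the all-zeros haplotype.
    """
    clades = [frozenset([i]) for i in range(n)]
    internal = []
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        merged = clades[i] | clades[j]
        internal.append(merged)
        clades = [c for idx, c in enumerate(clades) if idx not in (i, j)] + [merged]
    candidates = [frozenset([i]) for i in range(n)] + [c for c in internal if len(c) < n]
    cols = np.zeros((n, n_cols), dtype=np.int8)
    for j in range(n_cols):
        clade = candidates[rng.integers(len(candidates))]
        cols[list(clade), j] = 1
    poly = (cols.min(axis=0) == 0) & (cols.max(axis=0) == 1)
    while not poly.all():  # re-draw monomorphic columns
        for j in np.flatnonzero(~poly):
            clade = candidates[rng.integers(len(candidates))]
            cols[:, j] = 0
            cols[list(clade), j] = 1
        poly = (cols.min(axis=0) == 0) & (cols.max(axis=0) == 1)
    return cols


@pytest.fixture
def rng():
    return np.random.default_rng(20130620)


@pytest.fixture
def six_taxon_tree():
    """Fully resolved six-taxon tree: ((((0,1),2),3),((4,5))-style shape."""
    spec = (((0, 1), 2), (3, (4, 5)))
    lengths = {
        frozenset({0, 1, 2}): 0.2,
        frozenset({0, 1}): 0.3,
        frozenset({0}): 0.4,
        frozenset({1}): 0.4,
        frozenset({2}): 0.7,
        frozenset({3, 4, 5}): 0.1,
        frozenset({3}): 0.8,
        frozenset({4, 5}): 0.5,
        frozenset({4}): 0.3,
        frozenset({5}): 0.3,
    }
    return make_tree(spec, lengths)


@pytest.fixture
def four_tip_genealogy():
    """Balanced 4-tip genealogy: cherries (0,1) and (2,3), root at age 1."""
    # nodes 0-3 tips, 4 = mrca(0,1) at 0.3, 5 = mrca(2,3) at 0.6, 6 = root
    parent = np.array([4, 4, 5, 5, 6, 6, -1])
    time = np.array([0.0, 0.0, 0.0, 0.0, 0.3, 0.6, 1.0])
    return Genealogy(parent=parent, time=time, samples=np.arange(4))
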