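"""Local perfect phylogenies at a focal SNP.

At each SNP the evolutionary history of the sampled haplotypes is summarised
by a rooted *local tree* built from the maximal window of neighbouring SNPs
that are mutually compatible with a single tree.  The topology is the
(unique) perfect phylogeny of the windowed 0/1 matrix rooted at the all-zeros
ancestral haplotype; branch lengths are estimated from a most-parsimonious
ancestral-state reconstruction under the two-state Markov substitution model
(M2): for an edge whose endpoint state vectors differ at a proportion ``p``
of the window SNPs, the expected number of substitutions per site is

    d = -(1/2) * ln(1 - 2 p)

with ``p = 1/S_w`` substituted when the reconstruction shows no change
(keeping every edge length positive) and ``p`` capped just below 1/2 where
the formula diverges.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TreeNode",
    "LocalTree",
    "IncompatibleWindowError",
    "four_gamete_compatible",
    "compatible_window",
    "build_perfect_phylogeny",
    "fitch_ancestral_states",
    "estimate_branch_lengths",
    "build_local_tree",
]


class IncompatibleWindowError(ValueError):
    """Raised when a SNP window admits no rooted perfect phylogeny."""


class TreeNode:
    """Node of a rooted local tree.

    ``tip_id`` is the haplotype row index for leaves and ``None`` for
    internal nodes.  ``length`` is the branch length of the edge to the
    parent (unset for the root); ``depth`` is the root-to-node path length.
    """

    __slots__ = ("parent", "children", "length", "depth", "tip_id", "label", "tip_mask")

    def __init__(self, tip_id: int | None = None, label: str | None = None):
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.length: float = 0.0
        self.depth: float = 0.0
        self.tip_id = tip_id
        self.label = label
        self.tip_mask: np.ndarray | None = None  # boolean over haplotype rows

    @property
    def is_tip(self) -> bool:
        return self.tip_id is not None

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


class LocalTree:
    """Rooted local phylogeny whose tips are haplotype rows.

    Parameters
    ----------
    root
        Root node (the all-zeros ancestral haplotype).
    tips
        Tip nodes indexed by haplotype row.
    window
        Half-open SNP-index interval ``[lo, hi)`` of compatible SNPs the
        topology was built from.
    """

    def __init__(self, root: TreeNode, tips: Sequence[TreeNode], window: tuple[int, int]):
        self.root = root
        self.tips = list(tips)
        self.window = window
        self.node_states: dict[TreeNode, np.ndarray] = {}
        self._index_nodes()

    def _index_nodes(self) -> None:
        # preorder; tip masks for fast clade queries
        self.preorder_nodes: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            self.preorder_nodes.append(node)
            stack.extend(reversed(node.children))
        n = len(self.tips)
        for node in reversed(self.preorder_nodes):
            mask = np.zeros(n, dtype=bool)
            if node.is_tip:
                mask[node.tip_id] = True
            else:
                for child in node.children:
                    mask |= child.tip_mask
            node.tip_mask = mask

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def postorder(self) -> Iterator[TreeNode]:
        return reversed(self.preorder_nodes)

    def preorder(self) -> Iterator[TreeNode]:
        return iter(self.preorder_nodes)

    def compute_depths(self) -> None:
        for node in self.preorder_nodes:
            node.depth = 0.0 if node.parent is None else node.parent.depth + node.length

    def mrca(self, mask: np.ndarray) -> TreeNode:
        """Most recent common ancestor of the tips selected by ``mask``."""
        node = self.tips[int(np.flatnonzero(mask)[0])]
        while not np.all(node.tip_mask[mask]):
            node = node.parent
        return node

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                name = node.label if node.label is not None else f"t{node.tip_id}"
            else:
                inner = ",".join(fmt(c) for c in node.children)
                name = f"({inner})"
            if node.parent is None:
                return name
            return f"{name}:{node.length:.10g}"

        return fmt(self.root) + ";"


def four_gamete_compatible(col_a: np.ndarray, col_b: np.ndarray) -> bool:
    """Four-gamete test: True iff at most 3 of the gametes 00,01,10,11 occur."""
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape:
        raise ValueError("columns have different lengths")
    gametes = {(int(x), int(y)) for x, y in zip(a, b)}
    return len(gametes) <= 3


def _rooted_compatible(a: np.ndarray, b: np.ndarray) -> bool:
    # A 0-rooted perfect phylogeny exists iff derived (1) sets are nested or
    # disjoint, i.e. gametes 11, 10 and 01 never all occur.
    n11 = bool(np.any(a & b))
    n10 = bool(np.any(a & ~b))
    n01 = bool(np.any(~a & b))
    return not (n11 and n10 and n01)


def _cols_compatible(included: np.ndarray, candidate: np.ndarray) -> bool:
    """Rooted compatibility of one candidate column against a set of columns."""
    c = candidate[:, None].astype(bool)
    m = included.astype(bool)
    n11 = (m & c).any(axis=0)
    n10 = (~m & c).any(axis=0)
    n01 = (m & ~c).any(axis=0)
    return not bool(np.any(n11 & n10 & n01))


def compatible_window(matrix, focal: int) -> tuple[int, int]:
    """Maximal compatible SNP window around ``focal``, grown symmetrically.

    The window alternately extends one SNP to the left and to the right of the
    focal SNP; a side is closed permanently as soon as its next SNP is
    incompatible with any SNP already in the window.  Compatibility is the
    rooted (laminar derived-sets) criterion, which guarantees the windowed
    matrix admits a perfect phylogeny rooted at the all-zeros haplotype.
    """
    alleles = matrix.alleles
    n_snps = alleles.shape[1]
    if not 0 <= focal < n_snps:
        raise IndexError(f"focal SNP index {focal} out of range [0, {n_snps})")
    lo, hi = focal, focal + 1
    left_open, right_open = lo > 0, hi < n_snps
    try_left = True
    while left_open or right_open:
        if (try_left and left_open) or not right_open:
            cand = lo - 1
            if _cols_compatible(alleles[:, lo:hi], alleles[:, cand]):
                lo = cand
                left_open = lo > 0
            else:
                left_open = False
        elif right_open:
            cand = hi
            if _cols_compatible(alleles[:, lo:hi], alleles[:, cand]):
                hi = cand + 1
                right_open = hi < n_snps
            else:
                right_open = False
        try_left = not try_left
    return lo, hi


def build_perfect_phylogeny(submatrix: np.ndarray, labels: Sequence[str] | None = None) -> LocalTree:
    """Rooted perfect phylogeny of a compatible 0/1 matrix.

    The root is the all-zeros ancestral haplotype; every distinct non-singleton
    derived-allele set becomes one internal edge, and tips carrying identical
    row patterns attach as a polytomy under their smallest containing clade.

    Raises
    ------
    IncompatibleWindowError
        If the derived sets are not laminar (no 0-rooted tree exists).
    """
    sub = np.asarray(submatrix)
    n, n_cols = sub.shape
    if n_cols == 0:
        raise ValueError("empty SNP window")
    col_sets = np.unique(sub.T.astype(bool), axis=0)
    sizes = col_sets.sum(axis=1)
    # constant columns carry no split: all-zeros is the root state and an
    # all-ones column sits on the (absent) edge above the root
    keep = (sizes > 0) & (sizes < n)
    col_sets, sizes = col_sets[keep], sizes[keep]
    # laminar check: pairwise overlap must equal one of the two set sizes
    overlap = col_sets.astype(np.int64) @ col_sets.T.astype(np.int64)
    bad = (overlap > 0) & (overlap != sizes[:, None]) & (overlap != sizes[None, :])
    if np.any(bad):
        raise IncompatibleWindowError("window columns admit no rooted perfect phylogeny")

    # sort clades large-to-small (deterministic tie-break on the bit pattern)
    order = np.lexsort(tuple(col_sets.T) + (-sizes,))
    col_sets = col_sets[order]
    sizes = sizes[order]

    root = TreeNode()
    placed: list[tuple[np.ndarray, TreeNode]] = []  # in decreasing-size order
    for cs, size in zip(col_sets, sizes):
        if size == 1:
            continue  # singleton clades coincide with the tip's pendant edge
        parent = root
        for mask, node in placed:
            if mask[cs].all():
                parent = node  # smallest superset seen so far (scan is size-desc)
        node = TreeNode()
        parent.add_child(node)
        placed.append((cs, node))

    tips = []
    for i in range(n):
        parent = root
        for mask, node in placed:
            if mask[i]:
                parent = node
        tip = TreeNode(tip_id=i, label=labels[i] if labels is not None else None)
        parent.add_child(tip)
        tips.append(tip)
    return LocalTree(root, tips, window=(0, n_cols))


def fitch_ancestral_states(tree: LocalTree, submatrix: np.ndarray) -> dict[TreeNode, np.ndarray]:
    """Most-parsimonious binary ancestral states, valid on polytomies.

    Exact two-pass dynamic programme (Sankoff/Hartigan for two states):
    bottom-up subtree change-counts per state, then a top-down assignment that
    resolves ties toward the parent's state and root ties to state 0 (the
    ancestral allele).  Returns one state vector per node over the window
    SNPs; the minimum total number of changes is achieved per SNP.
    """
    sub = np.asarray(submatrix)
    n_snps = sub.shape[1]
    big = n_snps + 1  # effectively infinity for per-SNP change counts
    cost: dict[TreeNode, np.ndarray] = {}
    for node in tree.postorder():
        c = np.zeros((n_snps, 2), dtype=np.int64)
        if node.is_tip:
            obs = sub[node.tip_id].astype(np.int64)
            c[np.arange(n_snps), 1 - obs] = big
        else:
            for child in node.children:
                cc = cost[child]
                c[:, 0] += np.minimum(cc[:, 0], cc[:, 1] + 1)
                c[:, 1] += np.minimum(cc[:, 1], cc[:, 0] + 1)
        cost[node] = c

    states: dict[TreeNode, np.ndarray] = {}
    for node in tree.preorder():
        c = cost[node]
        if node.parent is None:
            state = (c[:, 1] < c[:, 0]).astype(np.int8)  # tie -> 0
        else:
            ps = states[node.parent]
            other = 1 - ps
            keep = c[np.arange(n_snps), ps] <= c[np.arange(n_snps), other] + 1
            state = np.where(keep, ps, other).astype(np.int8)
        states[node] = state
    return states


def estimate_branch_lengths(tree: LocalTree, node_states: dict[TreeNode, np.ndarray]) -> LocalTree:
    """M2-model branch lengths from reconstructed states (in place).

    p-hat is the proportion of window SNPs at which the two endpoint state
    vectors differ; zero proportions are replaced by 1/S_w and proportions at
    or above the divergence point of the M2 distance are capped at
    0.5 - 1/(2*max(S_w, 2)).
    """
    any_states = next(iter(node_states.values()))
    s_w = int(any_states.shape[0])
    if s_w == 0:
        raise ValueError("empty SNP window: cannot estimate branch lengths")
    p_cap = 0.5 - 1.0 / (2.0 * max(s_w, 2))
    for node in tree.preorder():
        if node.parent is None:
            continue
        p = float(np.mean(node_states[node] != node_states[node.parent]))
        if p == 0.0:
            p = 1.0 / s_w
        if p >= p_cap:
            p = p_cap
        node.length = -0.5 * math.log(1.0 - 2.0 * p)
    tree.node_states = node_states
    tree.compute_depths()
    return tree


def branch_length_from_p(p_hat: float, s_w: int) -> float:
    """M2 distance for a single difference proportion (same rules as above)."""
    if s_w < 1:
        raise ValueError("window must contain at least one SNP")
    p_cap = 0.5 - 1.0 / (2.0 * max(s_w, 2))
    if p_hat == 0.0:
        p_hat = 1.0 / s_w
    if p_hat >= p_cap:
        p_hat = p_cap
    return -0.5 * math.log(1.0 - 2.0 * p_hat)


def build_local_tree(matrix, focal: int) -> LocalTree:
    """Window -> topology -> parsimony states -> branch lengths at one SNP."""
    lo, hi = compatible_window(matrix, focal)
    sub = matrix.alleles[:, lo:hi]
    labels = getattr(matrix, "labels", None)
    tree = build_perfect_phylogeny(sub, labels=labels)
    tree.window = (lo, hi)
    states = fitch_ancestral_states(tree, sub)
    estimate_branch_lengths(tree, states)
    return tree
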