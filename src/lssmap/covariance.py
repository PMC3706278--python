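"""Cluster partitions from the earliest tree edges and their covariance.

Under a Brownian-motion model of trait evolution along a local tree the
covariance of two tips is proportional to the depth of their most recent
common ancestor (the length of shared history).  The score statistic uses a
coarsened version of this matrix: the tree is cut into ``k`` clusters by the
``k-1`` earliest edges (those whose parent is closest to the root) and the
covariance entries are replaced by cluster-level MRCA depths, so the matrix
carries only the broad-scale evolutionary relationships — O(k^2) distinct
values plus the tip-depth diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .local_tree import LocalTree, TreeNode

__all__ = [
    "ClusterPartition",
    "cluster_partition",
    "k_available",
    "clustered_covariance",
    "full_covariance",
    "RIDGE_EPSILON",
]

#: relative ridge added to every covariance matrix so duplicate haplotypes
#: (identical rows -> identical covariance rows) never make it singular
RIDGE_EPSILON = 1e-8


@dataclass
class ClusterPartition:
    """Tips grouped into k clusters by cutting the earliest (k-1) edges.

    ``assignment`` maps tip index to a contiguous label in ``1..k`` (labelled
    by first occurrence in tip order); ``cluster_root_depth[j]`` is the depth
    of cluster ``j+1``'s MRCA; ``cross_depth[i, j]`` the depth of the MRCA of
    clusters ``i+1`` and ``j+1`` (diagonal = ``cluster_root_depth``).
    """

    k: int
    assignment: np.ndarray
    cluster_root_depth: np.ndarray
    cross_depth: np.ndarray


def _edge_cut_sequence(tree: LocalTree) -> list[tuple[TreeNode, np.ndarray]]:
    """Effective earliest-edge cuts with the tip assignment after each cut.

    Internal non-root nodes are visited in "earliest" order — ascending depth
    of their parent, ties broken by preorder position — and an edge is cut
    only if doing so splits a nonempty group off an existing cluster (a
    redundant cut, e.g. the second child edge of a binary root, is skipped so
    every cluster stays nonempty).  Cached on the tree.
    """
    cached = getattr(tree, "_cut_sequence", None)
    if cached is not None:
        return cached
    order = [
        (node.parent.depth, idx, node)
        for idx, node in enumerate(tree.preorder_nodes)
        if node.parent is not None and not node.is_tip
    ]
    order.sort(key=lambda t: (t[0], t[1]))
    n = tree.n_tips
    assign = np.zeros(n, dtype=np.int64)  # raw ids; 0 = root component
    counts = {0: n}
    cuts: list[tuple[TreeNode, np.ndarray]] = []
    next_id = 1
    for _, _, node in order:
        tips = node.tip_mask
        size = int(tips.sum())
        current = int(assign[np.flatnonzero(tips)[0]])
        if counts[current] == size:
            continue  # would leave the donor cluster empty: same partition
        assign[tips] = next_id
        counts[current] -= size
        counts[next_id] = size
        next_id += 1
        cuts.append((node, assign.copy()))
    tree._cut_sequence = cuts
    return cuts


def k_available(tree: LocalTree) -> int:
    """Largest k for which an earliest-edges partition exists."""
    return len(_edge_cut_sequence(tree)) + 1


def cluster_partition(tree: LocalTree, k: int) -> ClusterPartition:
    """Partition of the tips defined by the earliest ``k-1`` edges."""
    if k < 1:
        raise ValueError("k must be >= 1")
    cuts = _edge_cut_sequence(tree)
    if k > len(cuts) + 1:
        raise ValueError(f"partition unavailable: k={k} > k_avail={len(cuts) + 1}")
    raw = np.zeros(tree.n_tips, dtype=np.int64) if k == 1 else cuts[k - 2][1]
    # contiguous labels 1..k in order of first occurrence along the tip order
    labels = {}
    assignment = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in labels:
            labels[r] = len(labels) + 1
        assignment[i] = labels[r]

    masks = [assignment == (j + 1) for j in range(k)]
    mrcas = [tree.mrca(m) for m in masks]
    root_depth = np.array([node.depth for node in mrcas])
    cross = np.empty((k, k))
    for i in range(k):
        cross[i, i] = root_depth[i]
        for j in range(i + 1, k):
            node = mrcas[i]
            union = masks[i] | masks[j]
            while not np.all(node.tip_mask[union]):
                node = node.parent
            cross[i, j] = cross[j, i] = node.depth
    return ClusterPartition(k=k, assignment=assignment, cluster_root_depth=root_depth, cross_depth=cross)


def _tip_depths(tree: LocalTree) -> np.ndarray:
    return np.array([tip.depth for tip in tree.tips])


def _add_ridge(V: np.ndarray) -> np.ndarray:
    scale = float(np.mean(np.diag(V)))
    V[np.diag_indices_from(V)] += RIDGE_EPSILON * scale
    return V


def clustered_covariance(tree: LocalTree, partition: ClusterPartition, ridge: bool = True) -> np.ndarray:
    """Tip covariance implied by the clustered tree.

    Off-diagonals carry the MRCA depth of the two tips' clusters (the shared
    cluster's root depth within a cluster); the diagonal keeps each tip's own
    full root-to-tip depth.  A relative ridge ``1e-8 * mean(diag)`` keeps the
    matrix positive definite.
    """
    idx = partition.assignment - 1
    V = partition.cross_depth[np.ix_(idx, idx)].copy()
    V[np.diag_indices_from(V)] = _tip_depths(tree)
    return _add_ridge(V) if ridge else V


def full_covariance(tree: LocalTree, ridge: bool = False) -> np.ndarray:
    """Un-clustered Brownian covariance: V[i, j] = depth of MRCA(i, j)."""
    n = tree.n_tips
    V = np.zeros((n, n))
    for node in tree.preorder():
        if node.is_tip:
            continue
        seen = np.zeros(n, dtype=bool)
        for child in node.children:
            m = child.tip_mask
            V[np.ix_(m, seen)] = node.depth
            V[np.ix_(seen, m)] = node.depth
            seen |= m
    V[np.diag_indices_from(V)] = _tip_depths(tree)
    return _add_ridge(V) if ridge else V
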