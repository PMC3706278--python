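import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lssmap.io import HaplotypeMatrix
from lssmap.local_tree import (
    IncompatibleWindowError,
    branch_length_from_p,
    build_local_tree,
    build_perfect_phylogeny,
    compatible_window,
    estimate_branch_lengths,
    fitch_ancestral_states,
    four_gamete_compatible,
)

from conftest import random_coalescent_matrix


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0, 0, 1, 1), (0, 1, 0, 1), False),  # all four gametes
        ((0, 1, 0, 1), (0, 1, 0, 1), True),  # identical columns
        ((0, 1, 1, 0), (1, 0, 0, 1), True),  # complementary: gametes 01, 10
        ((0, 0, 1, 1), (0, 0, 0, 1), True),  # nested derived sets
    ],
)
def test_four_gamete_test(a, b, expected):
    assert four_gamete_compatible(np.array(a), np.array(b)) is expected


def test_four_gamete_length_mismatch():
    with pytest.raises(ValueError):
        four_gamete_compatible(np.array([0, 1]), np.array([0, 1, 0]))


def _pairwise_rooted_ok(sub):
    for i, j in itertools.combinations(range(sub.shape[1]), 2):
        a, b = sub[:, i].astype(bool), sub[:, j].astype(bool)
        if (a & b).any() and (a & ~b).any() and (~a & b).any():
            return False
    return True


class TestCompatibleWindow:
    def test_fully_compatible_matrix_gives_whole_chromosome(self, rng):
        cols = random_coalescent_matrix(rng, n=8, n_cols=6)
        m = HaplotypeMatrix(cols, np.arange(1, 7))
        assert compatible_window(m, 3) == (0, 6)

    def test_isolated_focal_snp(self):
        # middle SNP incompatible with both neighbours
        alleles = np.array(
            [[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1], [0, 1, 0], [1, 0, 1]]
        )
        m = HaplotypeMatrix(alleles, np.array([10, 20, 30]))
        assert compatible_window(m, 1) == (1, 2)

    def test_truncation_matches_brute_force(self):
        # 5 SNPs with a conflict to the right of the focal SNP
        alleles = np.array(
            [
                [1, 1, 1, 0, 1],
                [1, 1, 1, 0, 0],
                [0, 1, 1, 1, 1],
                [0, 0, 1, 1, 0],
                [0, 0, 0, 1, 1],
                [0, 0, 0, 0, 0],
            ]
        )
        m = HaplotypeMatrix(alleles, np.arange(1, 6))
        focal = 1
        best = (focal, focal + 1)
        for lo in range(focal + 1):
            for hi in range(focal + 1, 6):
                if _pairwise_rooted_ok(alleles[:, lo:hi]) and hi - lo > best[1] - best[0]:
                    best = (lo, hi)
        got = compatible_window(m, focal)
        assert _pairwise_rooted_ok(alleles[:, got[0] : got[1]])
        assert got[1] - got[0] == best[1] - best[0]
        assert got == (0, 3)  # truncated exactly at the conflicting SNP

    def test_windows_always_contain_focal(self, rng):
        cols = rng.integers(0, 2, size=(10, 12)).astype(np.int8)
        cols[0] = 0
        cols[1] = 1  # keep every column polymorphic
        m = HaplotypeMatrix(cols, np.arange(1, 13))
        for focal in range(m.n_snps):
            lo, hi = compatible_window(m, focal)
            assert lo <= focal < hi
            assert _pairwise_rooted_ok(m.alleles[:, lo:hi])


def _induced_splits(tree):
    n = tree.n_tips
    splits = set()
    for node in tree.preorder():
        if node.parent is None:
            continue
        splits.add(frozenset(np.flatnonzero(node.tip_mask)))
    return splits


class TestPerfectPhylogeny:
    def test_caterpillar_from_nested_columns(self):
        sub = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]])
        tree = build_perfect_phylogeny(sub)
        col_splits = {frozenset(np.flatnonzero(sub[:, j])) for j in range(3)}
        assert col_splits <= _induced_splits(tree)

    def test_identical_rows_give_single_polytomy(self):
        sub = np.ones((5, 2), dtype=np.int8)
        tree = build_perfect_phylogeny(sub)
        assert len(tree.root.children) == 5
        assert all(c.is_tip for c in tree.root.children)

    def test_incompatible_columns_raise(self):
        sub = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        with pytest.raises(IncompatibleWindowError):
            build_perfect_phylogeny(sub)

    def test_splits_equal_column_bipartitions_on_random_fixtures(self, rng):
        for _ in range(25):
            sub = random_coalescent_matrix(rng, n=10, n_cols=8)
            tree = build_perfect_phylogeny(sub)
            col_splits = {frozenset(np.flatnonzero(sub[:, j])) for j in range(sub.shape[1])}
            induced = _induced_splits(tree)
            assert col_splits <= induced
            # and every internal edge is backed by some column
            internal = {s for s in induced if len(s) > 1}
            assert internal <= col_splits

    def test_internal_nodes_have_at_least_two_children(self, rng):
        for _ in range(10):
            sub = random_coalescent_matrix(rng, n=9, n_cols=7)
            tree = build_perfect_phylogeny(sub)
            for node in tree.preorder():
                if not node.is_tip:
                    assert len(node.children) >= 2


def _brute_force_parsimony(tree, sub):
    """Minimum total state changes over all internal-node assignments."""
    internal = [n for n in tree.preorder() if not n.is_tip]
    total = 0
    for j in range(sub.shape[1]):
        best = math.inf
        for states in itertools.product((0, 1), repeat=len(internal)):
            assign = dict(zip(internal, states))
            for tip in tree.tips:
                assign[tip] = sub[tip.tip_id, j]
            changes = sum(
                assign[n] != assign[n.parent] for n in tree.preorder() if n.parent is not None
            )
            best = min(best, changes)
        total += best
    return total


class TestFitch:
    def test_perfect_phylogeny_has_one_change_per_snp(self, rng):
        sub = random_coalescent_matrix(rng, n=8, n_cols=6)
        tree = build_perfect_phylogeny(sub)
        states = fitch_ancestral_states(tree, sub)
        changes = np.zeros(sub.shape[1], dtype=int)
        for node in tree.preorder():
            if node.parent is not None:
                changes += states[node] != states[node.parent]
        assert (changes == 1).all()

    def test_matches_exhaustive_minimum_on_small_trees(self, rng):
        for _ in range(8):
            sub = random_coalescent_matrix(rng, n=5, n_cols=4)
            # score arbitrary (possibly conflicting) data on an arbitrary tree
            other = rng.integers(0, 2, size=(5, 4)).astype(np.int8)
            tree = build_perfect_phylogeny(sub)
            states = fitch_ancestral_states(tree, other)
            got = sum(
                int(np.sum(states[n] != states[n.parent]))
                for n in tree.preorder()
                if n.parent is not None
            )
            assert got == _brute_force_parsimony(tree, other)

    def test_root_state_is_ancestral_zero_on_perfect_input(self, rng):
        sub = random_coalescent_matrix(rng, n=8, n_cols=6)
        tree = build_perfect_phylogeny(sub)
        states = fitch_ancestral_states(tree, sub)
        assert not states[tree.root].any()


class TestBranchLengths:
    def test_m2_distance_examples(self):
        assert branch_length_from_p(0.25, 100) == pytest.approx(-0.5 * math.log(0.5))
        assert branch_length_from_p(0.25, 100) == pytest.approx(0.346574, abs=1e-6)
        # zero proportion replaced by 1/S_w
        assert branch_length_from_p(0.0, 100) == pytest.approx(-0.5 * math.log(0.98))
        assert branch_length_from_p(0.0, 100) == pytest.approx(0.010101, abs=1e-6)
        # divergent proportions capped just below 1/2
        capped = branch_length_from_p(0.5, 10)
        assert capped == pytest.approx(-0.5 * math.log(1 - 2 * 0.45))
        assert math.isfinite(capped)

    def test_distance_increasing_in_p(self):
        ps = np.linspace(0.01, 0.44, 40)
        ds = [branch_length_from_p(p, 1000) for p in ps]
        assert np.all(np.diff(ds) > 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        p1=st.floats(0.001, 0.498),
        p2=st.floats(0.001, 0.498),
        s_w=st.integers(2, 10_000),
    )
    def test_distance_monotone_and_finite_for_any_window(self, p1, p2, s_w):
        lo, hi = sorted((p1, p2))
        d_lo, d_hi = branch_length_from_p(lo, s_w), branch_length_from_p(hi, s_w)
        assert 0 < d_lo <= d_hi
        assert math.isfinite(d_hi)

    def test_estimated_trees_have_positive_finite_depths(self, rng):
        for _ in range(10):
            sub = random_coalescent_matrix(rng, n=8, n_cols=5)
            tree = build_perfect_phylogeny(sub)
            states = fitch_ancestral_states(tree, sub)
            estimate_branch_lengths(tree, states)
            for tip in tree.tips:
                assert np.isfinite(tip.depth) and tip.depth > 0

    def test_single_snp_window_stays_usable(self):
        alleles = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1], [0, 1, 0], [1, 0, 1]])
        m = HaplotypeMatrix(alleles, np.array([10, 20, 30]))
        tree = build_local_tree(m, 1)
        assert tree.window == (1, 2)
        for tip in tree.tips:
            assert tip.depth > 0


def test_newick_roundtrips_labels_and_lengths(rng):
    sub = random_coalescent_matrix(rng, n=6, n_cols=4)
    m = HaplotypeMatrix(sub, np.arange(1, 5))
    tree = build_local_tree(m, 0)
    nwk = tree.newick()
    assert nwk.endswith(";")
    for label in m.labels:
        assert label in nwk
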