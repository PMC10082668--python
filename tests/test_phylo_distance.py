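import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from flexms.flex_extraction import build_target_set
from flexms.io_formats import FeatureTable, read_newick
from flexms.marker_selection import MarkerSet
from flexms.phylo_distance import (
    ConsistencyState,
    combine_children,
    fms_distance,
    global_distance,
    leaf_consistency,
    pairwise_matrix,
    tree_consistency,
)

from conftest import random_table, random_tree


def oracle_consistency(newick: str, v1: dict, v2: dict) -> float:
    """Independent straight-line recursion on a dendropy-parsed tree.

    Children are pooled at once (equivalent to pairwise matching because
    residuals are one-sided): each child's residuals are attenuated by
    max(0, 1 - branch length), opposite-sample pools are matched, and the
    matched mass accumulates to the root.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")

    def rec(node):
        if node.is_leaf():
            a1 = float(v1.get(node.taxon.label, 0.0))
            a2 = float(v2.get(node.taxon.label, 0.0))
            m = min(a1, a2)
            return [m, a1 - m, a2 - m]
        con = p1 = p2 = 0.0
        for ch in node.child_nodes():
            c, r1, r2 = rec(ch)
            att = max(0.0, 1.0 - (ch.edge.length or 0.0))
            con += c
            p1 += r1 * att
            p2 += r2 * att
        extra = min(p1, p2)
        return [con + extra, p1 - extra, p2 - extra]

    return rec(tree.seed_node)[0]


class TestLeafAndCombine:
    @pytest.mark.parametrize(
        "a1,a2,con,r1,r2",
        [(0.3, 0.2, 0.2, 0.1, 0.0), (0.0, 0.4, 0.0, 0.0, 0.4),
         (0.25, 0.25, 0.25, 0.0, 0.0)],
    )
    def test_leaf_consistency(self, a1, a2, con, r1, r2):
        s = leaf_consistency(a1, a2)
        assert (s.con, s.r1, s.r2) == pytest.approx((con, r1, r2))

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            leaf_consistency(-0.1, 0.2)

    def test_opposite_residuals_match_attenuated(self):
        a = ConsistencyState(con=0.0, r1=0.1, r2=0.0)
        b = ConsistencyState(con=0.0, r1=0.0, r2=0.08)
        out = combine_children([a, b], [0.1, 0.1])
        # min(0.1*0.9, 0.08*0.9) = 0.072 matched
        assert out.con == pytest.approx(0.072)
        assert out.r1 == pytest.approx(0.09 - 0.072)
        assert out.r2 == pytest.approx(0.0)

    def test_same_side_surpluses_pool_without_matching(self):
        a = ConsistencyState(con=0.0, r1=0.1, r2=0.0)
        b = ConsistencyState(con=0.0, r1=0.2, r2=0.0)
        out = combine_children([a, b], [0.0, 0.0])
        assert out.con == 0.0
        assert out.r1 == pytest.approx(0.3)

    def test_branch_length_above_one_blocks_matching(self):
        a = ConsistencyState(con=0.0, r1=0.5, r2=0.0)
        b = ConsistencyState(con=0.0, r1=0.0, r2=0.5)
        out = combine_children([a, b], [1.5, 0.0])
        assert out.con == 0.0

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            combine_children([ConsistencyState(0, 0, 0)] * 2, [0.1, -0.2])


class TestTreeConsistency:
    def test_identical_vectors_match_total_mass(self):
        tree = read_newick("((A:0.3,B:0.2):0.1,C:0.4);")
        v = pd.Series({"A": 0.2, "B": 0.3, "C": 0.5})
        assert tree_consistency(v, v, tree) == pytest.approx(1.0)

    def test_two_leaf_hand_computation(self):
        tree = read_newick("(A:0.25,B:0.25);")
        v1 = pd.Series({"A": 0.3})
        v2 = pd.Series({"B": 0.2})
        # min(0.3*0.75, 0.2*0.75) = 0.15
        assert tree_consistency(v1, v2, tree) == pytest.approx(0.15)

    def test_saturating_branches_give_zero(self):
        tree = read_newick("(A:1.0,B:1.2);")
        v1 = pd.Series({"A": 0.6})
        v2 = pd.Series({"B": 0.6})
        assert tree_consistency(v1, v2, tree) == 0.0

    def test_member_missing_from_tree_is_error(self):
        tree = read_newick("(A:0.1,B:0.1);")
        with pytest.raises(KeyError, match="ZZ"):
            tree_consistency(pd.Series({"ZZ": 0.5}), pd.Series({"A": 0.5}), tree)

    def test_cherry_grid_matches_closed_form(self):
        # all 2-leaf configurations over an abundance grid vs the closed
        # form: sum of leaf minima + min((1-d1)+ * surplus1, (1-d2)+ * surplus2)
        grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
        for d1, d2 in [(0.0, 0.0), (0.25, 0.25), (0.1, 0.6), (0.9, 1.3)]:
            tree = read_newick(f"(A:{d1},B:{d2});")
            for a1, a2, b1, b2 in itertools.product(grid, repeat=4):
                v1 = pd.Series({"A": a1, "B": b1})
                v2 = pd.Series({"A": a2, "B": b2})
                leaf_min = min(a1, a2) + min(b1, b2)
                p1 = (a1 - min(a1, a2)) * max(0, 1 - d1) + (b1 - min(b1, b2)) * max(0, 1 - d2)
                p2 = (a2 - min(a1, a2)) * max(0, 1 - d1) + (b2 - min(b1, b2)) * max(0, 1 - d2)
                expected = leaf_min + min(p1, p2)
                assert tree_consistency(v1, v2, tree) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_random_trees_match_independent_recursion(self):
        rng = np.random.default_rng(5)
        for rep in range(15):
            n = int(rng.integers(3, 25))
            tree, leaves = random_tree(rng, n)
            newick = str(tree.tree)
            v1 = {l: float(x) for l, x in zip(leaves, rng.dirichlet(np.ones(n)))}
            v2 = {l: float(x) for l, x in zip(leaves, rng.dirichlet(np.ones(n)))}
            got = tree_consistency(pd.Series(v1), pd.Series(v2), tree)
            assert got == pytest.approx(oracle_consistency(newick, v1, v2), abs=1e-9)

    def test_consistency_bounded_by_min_mass(self):
        rng = np.random.default_rng(6)
        for rep in range(10):
            n = int(rng.integers(2, 15))
            tree, leaves = random_tree(rng, n)
            v1 = pd.Series(rng.gamma(1, 1, n), index=leaves)
            v2 = pd.Series(rng.gamma(1, 1, n), index=leaves)
            con = tree_consistency(v1, v2, tree)
            assert con <= min(v1.sum(), v2.sum()) + 1e-12

    def test_longer_branches_never_increase_consistency(self):
        rng = np.random.default_rng(7)
        tree, leaves = random_tree(rng, 10)
        v1 = pd.Series(rng.dirichlet(np.ones(10)), index=leaves)
        v2 = pd.Series(rng.dirichlet(np.ones(10)), index=leaves)
        base = tree_consistency(v1, v2, tree)
        for node in list(tree.tree.traverse(include_self=False))[:6]:
            node.length += 0.2
            assert tree_consistency(v1, v2, tree) <= base + 1e-12
            node.length -= 0.2


def _two_leaf_setup():
    tree = read_newick("((A:0.25,B:0.25):0.1,C:0.2);")
    df = pd.DataFrame(
        {"s1": [0.3, 0.0, 0.7], "s2": [0.0, 0.2, 0.8], "s3": [0.3, 0.0, 0.7]},
        index=["A", "B", "C"],
    )
    table = FeatureTable(df)
    target = build_target_set(MarkerSet(exact={"A", "B"}), None)
    return tree, table, target


class TestDistances:
    def test_identical_samples_distance_zero(self):
        tree, table, target = _two_leaf_setup()
        assert fms_distance(table, "s1", "s3", target, tree) == pytest.approx(0.0)
        assert global_distance(table, "s1", "s3", tree) == pytest.approx(0.0)

    def test_renormalized_cherry_distance(self):
        tree, table, target = _two_leaf_setup()
        # after renormalization over T the samples sit fully on opposite
        # cherry leaves: distance = 1 - 0.75 = 0.25
        assert fms_distance(table, "s1", "s2", target, tree) == pytest.approx(0.25)

    def test_disjoint_saturated_supports_distance_one(self):
        tree = read_newick("(A:1.0,B:1.0);")
        table = FeatureTable(
            pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]}, index=["A", "B"])
        )
        target = build_target_set(MarkerSet(exact={"A", "B"}), None)
        assert fms_distance(table, "s1", "s2", target, tree) == pytest.approx(1.0)

    def test_zero_mass_on_target_gives_distance_one(self, caplog):
        tree = read_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        table = FeatureTable(
            pd.DataFrame(
                {"s1": [0.0, 0.5, 0.5], "s2": [0.0, 0.2, 0.8]}, index=["A", "B", "C"]
            )
        )
        target = build_target_set(MarkerSet(exact={"A"}), None)
        with caplog.at_level("WARNING"):
            d = fms_distance(table, "s1", "s2", target, tree)
        assert d == 1.0
        assert "zero mass" in caplog.text

    def test_fms_with_all_features_equals_global(self, tiny_bundle):
        b = tiny_bundle
        target = build_target_set(MarkerSet(exact=set(b.table.feature_ids)), None)
        dm_fms = pairwise_matrix(b.table, b.tree, target=target)
        dm_glob = pairwise_matrix(b.table, b.tree, target=None)
        assert np.array_equal(dm_fms.data, dm_glob.data)

    def test_small_perturbation_gives_small_distance(self):
        tree = read_newick("(A:0.2,B:0.2);")
        for eps in (1e-3, 1e-5):
            table = FeatureTable(
                pd.DataFrame(
                    {"s1": [0.5, 0.5], "s2": [0.5 + eps, 0.5 - eps]},
                    index=["A", "B"],
                )
            )
            d = global_distance(table, "s1", "s2", tree)
            assert 0 <= d <= 2.5 * eps


class TestPairwiseMatrix:
    def test_identical_samples_zero_matrix(self):
        tree = read_newick("(A:0.1,B:0.1);")
        df = pd.DataFrame(
            np.tile([[0.4], [0.6]], (1, 3)), index=["A", "B"],
            columns=["s1", "s2", "s3"],
        )
        dm = pairwise_matrix(FeatureTable(df), tree)
        assert np.allclose(dm.data, 0.0)

    def test_matrix_matches_scalar_path_and_is_symmetric(self):
        rng = np.random.default_rng(8)
        tree, leaves = random_tree(rng, 12)
        table = random_table(rng, leaves, 6)
        dm = pairwise_matrix(table, tree)
        assert np.array_equal(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)
        for i, j in [(0, 1), (2, 5), (3, 4)]:
            s1, s2 = table.sample_ids[i], table.sample_ids[j]
            assert dm[s1, s2] == pytest.approx(
                global_distance(table, s1, s2, tree), abs=1e-12
            )

    def test_thread_count_does_not_change_bytes(self):
        rng = np.random.default_rng(9)
        tree, leaves = random_tree(rng, 8)
        table = random_table(rng, leaves, 5)
        d1 = pairwise_matrix(table, tree, threads=1)
        d4 = pairwise_matrix(table, tree, threads=4)
        assert d1.data.tobytes() == d4.data.tobytes()

    def test_target_member_absent_from_tree_is_error(self):
        tree = read_newick("(A:0.1,B:0.1);")
        table = FeatureTable(
            pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.2, 0.8]}, index=["A", "X"])
        )
        target = build_target_set(MarkerSet(exact={"A", "X"}), None)
        with pytest.raises(KeyError, match="X"):
            pairwise_matrix(table, tree, target=target)
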