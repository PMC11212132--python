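"""Neighbor joining and unrooted monophyly."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from _util import graph_monophyly, random_binary_tree
from ureidoscan.phylo import bipartitions, is_monophyletic, nj_tree
from ureidoscan.records import newick_string, read_newick


def additive_matrix(tree):
    dm = tree.tip_tip_distances()
    return DistanceMatrix(dm.data, list(dm.ids))


class TestNjTree:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], list("abc"))
        assert newick_string(nj_tree(dm)) == "(a:1.0,b:2.0,c:3.0);"

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], list("ab"))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(dm)

    def test_recovers_known_five_taxon_tree(self):
        # the classic worked example: ((a,b),c) with d,e on the other side
        dm = DistanceMatrix(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            list("abcde"),
        )
        tree = nj_tree(dm)
        out = tree.tip_tip_distances()
        for i, j in itertools.combinations("abcde", 2):
            assert out[i, j] == pytest.approx(dm[i, j], abs=1e-9)
        assert is_monophyletic(tree, {"a", "b"})
        assert is_monophyletic(tree, {"d", "e"})

    def test_additive_five_leaf_matrices_recovered_exactly(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            truth = random_binary_tree(rng, [f"t{i}" for i in range(5)])
            dm = additive_matrix(truth)
            got = nj_tree(dm)
            out = got.tip_tip_distances()
            for i, j in itertools.combinations(dm.ids, 2):
                assert abs(out[i, j] - dm[i, j]) < 1e-9
            assert bipartitions(got) == bipartitions(truth)

    def test_six_leaf_topology_recovery_property(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            truth = random_binary_tree(rng, [f"t{i}" for i in range(6)])
            got = nj_tree(additive_matrix(truth))
            assert bipartitions(got) == bipartitions(truth)

    def test_four_taxa_agree_with_least_squares_oracle(self):
        """NJ picks the 4-leaf topology with the best least-squares fit."""
        rng = np.random.default_rng(17)
        ids = list("abcd")
        pairs = list(itertools.combinations(range(4), 2))

        def ls_residual(D, split):
            # unrooted 4-leaf tree: 4 pendant edges + 1 internal edge
            (i, j), (k, l) = split
            rows, y = [], []
            for (u, v) in pairs:
                row = [0.0] * 5
                row[u] = 1.0
                row[v] = 1.0
                same_side = {u, v} in ({i, j}, {k, l})
                if not same_side:
                    row[4] = 1.0
                rows.append(row)
                y.append(D[u, v])
            _, res, _, _ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
            return float(res[0]) if len(res) else 0.0

        splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        for _ in range(20):
            truth = random_binary_tree(rng, ids)
            D = additive_matrix(truth).data + rng.uniform(0, 0.05, size=(4, 4))
            D = (D + D.T) / 2.0
            np.fill_diagonal(D, 0.0)
            tree = nj_tree(DistanceMatrix(D, ids))
            nj_split = next(s for s in bipartitions(tree) if len(s) == 2)
            best = min(splits, key=lambda s: ls_residual(D, s))
            expected = frozenset(ids[x] for x in best[0])
            complement = frozenset(ids[x] for x in best[1])
            assert nj_split in (expected, complement)

    def test_deterministic_under_ties(self):
        dm = DistanceMatrix((np.ones((4, 4)) - np.eye(4)), list("abcd"))
        assert newick_string(nj_tree(dm)) == newick_string(nj_tree(dm))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(55)
        for _ in range(20):
            n = 6
            M = rng.uniform(0.1, 2.0, size=(n, n))
            M = (M + M.T) / 2.0
            np.fill_diagonal(M, 0.0)
            tree = nj_tree(DistanceMatrix(M, [f"x{i}" for i in range(n)]))
            for node in tree.traverse(include_self=False):
                assert node.length >= 0.0

    def test_topology_agrees_with_skbio_nj(self):
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(13)
        for _ in range(10):
            truth = random_binary_tree(rng, [f"t{i}" for i in range(7)])
            D = additive_matrix(truth).data + rng.uniform(0, 0.02, size=(7, 7))
            D = (D + D.T) / 2.0
            np.fill_diagonal(D, 0.0)
            dm = DistanceMatrix(D, [f"t{i}" for i in range(7)])
            assert bipartitions(nj_tree(dm)) == bipartitions(skbio_nj(dm))


class TestIsMonophyletic:
    def test_simple_quartet(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert is_monophyletic(tree, {"a", "b"})
        assert not is_monophyletic(tree, {"a", "c"})

    def test_unknown_leaf_is_an_error(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(tree, {"a", "z"})

    def test_empty_subset_is_an_error(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="nonempty"):
            is_monophyletic(tree, set())

    def test_agrees_with_graph_oracle_on_random_trees(self):
        rng = np.random.default_rng(23)
        leaves = [f"t{i}" for i in range(8)]
        for _ in range(15):
            tree = random_binary_tree(rng, leaves)
            for _ in range(8):
                k = int(rng.integers(1, 8))
                subset = set(rng.choice(leaves, size=k, replace=False))
                assert is_monophyletic(tree, subset) == graph_monophyly(tree, subset)
            # every true clade must test monophyletic
            for node in tree.traverse(include_self=False):
                if not node.is_tip():
                    clade = {t.name for t in node.tips()}
                    assert is_monophyletic(tree, clade)
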