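"""Tree model, patristic distances, splits and pruning."""

import itertools

import dendropy
import numpy as np
import pytest

from fslb import Bipartition, MissingBranchLengthError, PhyloError, PhyloTree, splits_compatible
from fslb.simulate import random_binary_tree


def dendropy_distances(newick: str):
    """Independent patristic-distance oracle via dendropy's PDM."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


class TestPatristicDistances:
    def test_two_tip_path_sum(self):
        d = PhyloTree.from_newick("(A:1.0,B:2.0);").patristic_distance_matrix()
        assert d.loc["A", "B"] == pytest.approx(3.0)

    def test_quartet_path(self, quartet_tree):
        d = quartet_tree.patristic_distance_matrix()
        assert d.loc["A", "C"] == pytest.approx(14.0)  # 1+3+6+4
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle_on_random_trees(self, seed):
        tree = random_binary_tree(20, np.random.default_rng(seed))
        newick = tree.to_newick()
        d = tree.patristic_distance_matrix()
        oracle = dendropy_distances(newick)
        for pair, expected in oracle.items():
            a, b = sorted(pair)
            # oracle reads the 6-decimal serialization, so compare at that precision
            assert d.loc[a, b] == pytest.approx(expected, abs=2e-5)

    def test_missing_length_rejected_with_edge_named(self):
        tree = PhyloTree.from_newick("((A:1,B):3,(C:4,D:5):6);")
        with pytest.raises(MissingBranchLengthError, match="B"):
            tree.patristic_distance_matrix()

    def test_four_point_condition_on_random_trees(self, rng):
        tree = random_binary_tree(8, rng)
        d = tree.patristic_distance_matrix()
        labels = list(d.index)
        for q in itertools.combinations(labels, 4):
            i, j, k, l = q
            sums = sorted(
                [
                    d.loc[i, j] + d.loc[k, l],
                    d.loc[i, k] + d.loc[j, l],
                    d.loc[i, l] + d.loc[j, k],
                ]
            )
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)


class TestSplits:
    def test_single_internal_edge(self):
        splits = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);").splits_of()
        assert splits == {Bipartition({"A", "B"}, {"C", "D"})}

    def test_star_tree_has_no_splits(self):
        assert PhyloTree.from_newick("(A:1,B:1,C:1,D:1);").splits_of() == set()

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_binary_tree_has_n_minus_3_splits(self, n, rng):
        tree = random_binary_tree(n, rng)
        assert len(tree.splits_of()) == n - 3

    def test_splits_of_tree_mutually_compatible(self, rng):
        splits = list(random_binary_tree(10, rng).splits_of())
        for a, b in itertools.combinations(splits, 2):
            assert splits_compatible(a, b)

    def test_support_read_from_internal_labels(self):
        tree = PhyloTree.from_newick("((A:1,B:1)85:1,(C:1,D:1)40:1);")
        support = tree.split_support_map()
        assert support[Bipartition({"A", "B"}, {"C", "D"})] == 85.0


def all_trees(labels):
    """Every unrooted binary topology on the labels (edge-insertion oracle)."""
    if len(labels) == 3:
        root = ",".join(labels)
        yield f"({root});"
        return
    # represent as nested tuples and insert sequentially
    def insert_all(tree, label):
        if isinstance(tree, str):
            yield (tree, label)
            return
        left, right = tree
        yield (tree, label)
        for sub in insert_all(left, label):
            yield (sub, right)
        for sub in insert_all(right, label):
            yield (left, sub)

    def build(labels):
        if len(labels) == 1:
            yield labels[0]
            return
        for sub in build(labels[:-1]):
            yield from insert_all(sub, labels[-1])

    def tips(t):
        return [t] if isinstance(t, str) else tips(t[0]) + tips(t[1])

    def fmt(t):
        return t if isinstance(t, str) else f"({fmt(t[0])},{fmt(t[1])})"

    seen = set()
    first, rest = labels[0], labels[1:]
    for sub in build(rest):
        newick = f"({first},{fmt(sub)});"
        if newick not in seen:
            seen.add(newick)
            yield newick


def displayed_splits(newick):
    tree = PhyloTree.from_newick(newick)
    return tree.splits_of()


class TestCompatibility:
    def test_split_compatible_with_itself(self):
        a = Bipartition({"A", "B"}, {"C", "D"})
        assert splits_compatible(a, a)

    def test_conflicting_quartet_splits(self):
        a = Bipartition({"A", "B"}, {"C", "D"})
        b = Bipartition({"A", "C"}, {"B", "D"})
        assert not splits_compatible(a, b)

    def test_disjoint_universes_rejected(self):
        a = Bipartition({"A", "B"}, {"C", "D"})
        b = Bipartition({"E", "F"}, {"G", "H"})
        with pytest.raises(PhyloError):
            splits_compatible(a, b)

    def test_agrees_with_exhaustive_tree_search_on_six_taxa(self):
        labels = list("ABCDEF")
        # all non-trivial splits on 6 taxa
        splits = []
        for r in (2, 3):
            for side in itertools.combinations(labels, r):
                rest = [l for l in labels if l not in side]
                if r == 3 and "A" not in side:
                    continue  # avoid double-counting complementary 3|3 splits
                splits.append(Bipartition(side, rest))
        display = {s: set() for s in splits}
        for ti, newick in enumerate(all_trees(labels)):
            shown = displayed_splits(newick)
            for s in splits:
                if s in shown:
                    display[s].add(ti)
        for a, b in itertools.combinations(splits, 2):
            some_tree_shows_both = bool(display[a] & display[b])
            assert splits_compatible(a, b) == some_tree_shows_both, (a, b)


class TestPruning:
    def test_drop_one_keeps_other_distances(self, quartet_tree):
        pruned = quartet_tree.prune_taxa({"C"})
        assert pruned.patristic_distance_matrix().loc["A", "D"] == pytest.approx(15.0)

    def test_drop_nothing_is_identity(self, quartet_tree):
        before = quartet_tree.patristic_distance_matrix()
        after = quartet_tree.prune_taxa(set()).patristic_distance_matrix()
        assert np.allclose(before.values, after.loc[before.index, before.columns].values)

    @pytest.mark.parametrize("seed", range(5))
    def test_pruned_distances_equal_submatrix(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(12, rng)
        full = tree.patristic_distance_matrix()
        labels = list(full.index)
        drop = set(rng.choice(labels, size=5, replace=False))
        keep = [l for l in labels if l not in drop]
        pruned = tree.prune_taxa(drop).patristic_distance_matrix()
        assert np.allclose(pruned.loc[keep, keep].values, full.loc[keep, keep].values)

    def test_no_degree_two_nodes_after_pruning(self, quartet_tree):
        pruned = quartet_tree.prune_taxa({"C"})
        for node in pruned.preorder():
            if not node.is_leaf and node is not pruned.root:
                assert len(node.children) >= 2

    def test_overpruning_rejected(self, quartet_tree):
        with pytest.raises(PhyloError):
            quartet_tree.prune_taxa({"A", "B", "C"})


class TestNewickIO:
    def test_round_trip_preserves_distances(self, rng):
        tree = random_binary_tree(15, rng)
        again = PhyloTree.from_newick(tree.to_newick(precision=6))
        d1 = tree.patristic_distance_matrix()
        d2 = again.patristic_distance_matrix()
        assert np.allclose(d1.values, d2.loc[d1.index, d1.columns].values, atol=1e-5)

    def test_quoted_labels(self):
        tree = PhyloTree.from_newick("('taxon one':1,'taxon two':2);")
        assert set(tree.tip_labels) == {"taxon one", "taxon two"}
        again = PhyloTree.from_newick(tree.to_newick())
        assert set(again.tip_labels) == {"taxon one", "taxon two"}

    def test_writer_is_byte_stable(self, rng):
        tree = random_binary_tree(10, rng)
        assert tree.to_newick() == tree.to_newick()

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(PhyloError):
            PhyloTree.from_newick("((A:1,A:1):1,B:1);")

    def test_negative_length_rejected(self):
        with pytest.raises(PhyloError):
            PhyloTree.from_newick("((A:1,B:-0.5):1,C:1);")
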