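"""Distance engine, neighbor joining, bootstrap support and conflict screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fslb import (
    Alignment,
    Bipartition,
    CladeDefinition,
    DistanceEngine,
    GammaRates,
    PhyloTree,
    bootstrap_support,
    clade_support,
    conflicting_bipartitions,
    distance_matrix,
    model_corrected_distance,
    neighbor_joining,
)
from fslb.inference import T_MAX, cell_seed, impute_undefined
from fslb.simulate import random_binary_tree, simulate_alignment


class TestModelCorrectedDistance:
    def test_identical_sequences_have_zero_distance(self, lg):
        assert model_corrected_distance("ARNDC", "ARNDC", lg) == 0.0

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.4, 0.6, 0.8])
    def test_matches_poisson_closed_form(self, poisson, p):
        # 100-site pair with exactly 100*p differing positions
        n, k = 100, int(round(100 * p))
        a = "A" * n
        b = "R" * k + "A" * (n - k)
        t_hat = model_corrected_distance(a, b, poisson)
        expected = -(19 / 20) * np.log(1 - (20 / 19) * p)
        assert t_hat == pytest.approx(expected, abs=1e-6)

    def test_saturation_caps_at_t_max(self, poisson):
        # >= 19/20 observed differences: likelihood rises to the boundary
        a = "ARNDCQEGHILKMFPSTWYV" * 5
        b = "RNDCQEGHILKMFPSTWYVA" * 5
        assert model_corrected_distance(a, b, poisson) == T_MAX

    def test_no_shared_columns_is_undefined(self, lg):
        assert np.isnan(model_corrected_distance("AR--", "--ND", lg))

    def test_grid_engine_agrees_with_exact(self, lg, rng):
        tree = random_binary_tree(6, rng)
        aln, _ = simulate_alignment(tree, lg, GammaRates(1.0, 4), 500, seed=8)
        exact = distance_matrix(aln, lg, method="exact").to_numpy()
        grid = distance_matrix(aln, lg, method="grid").to_numpy()
        assert np.allclose(exact, grid, atol=2e-3)

    def test_imputation_fills_with_matrix_maximum(self):
        D = np.array([[0.0, 1.0, np.nan], [1.0, 0.0, 2.0], [np.nan, 2.0, 0.0]])
        out = impute_undefined(D)
        assert out[0, 2] == 2.0
        assert not np.isnan(out).any()


class TestNeighborJoining:
    def test_three_taxa_solves_pairwise_equations(self):
        D = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        tree = neighbor_joining(D)
        d = tree.patristic_distance_matrix()
        assert d.loc["A", "B"] == pytest.approx(5.0)
        assert d.loc["A", "C"] == pytest.approx(9.0)
        assert d.loc["B", "C"] == pytest.approx(10.0)

    def test_additive_quartet_recovers_topology_and_lengths(self, quartet_tree):
        D = quartet_tree.patristic_distance_matrix()
        tree = neighbor_joining(D)
        assert tree.splits_of() == {Bipartition({"A", "B"}, {"C", "D"})}
        d = tree.patristic_distance_matrix()
        assert np.allclose(d.loc[D.index, D.columns].values, D.values, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_consistency_on_additive_matrices(self, seed):
        tree = random_binary_tree(10, np.random.default_rng(seed))
        D = tree.patristic_distance_matrix()
        recovered = neighbor_joining(D)
        assert recovered.splits_of() == tree.splits_of()

    def test_negative_lengths_clamped_sum_preserved(self):
        # A non-additive matrix that drives one NJ branch negative.
        labels = list("ABCD")
        D = pd.DataFrame(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 0.1], [4, 4, 0.1, 0]],
            index=labels, columns=labels, dtype=float,
        )
        tree = neighbor_joining(D)
        for node in tree.preorder():
            if node is not tree.root:
                assert node.length >= 0.0

    def test_undefined_distances_rejected(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"), columns=list("ABC"))
        D.iloc[0, 1] = D.iloc[1, 0] = np.nan
        with pytest.raises(ValueError):
            neighbor_joining(D)


@pytest.fixture(scope="module")
def treelike_alignment():
    """Strong tree-like signal: long internal branch, 1000 sites."""
    from fslb import lg_model

    tree = PhyloTree.from_newick(
        "(((A:0.1,B:0.1):0.5,(C:0.1,D:0.1):0.5):0.05,(E:0.1,F:0.1):0.5);"
    )
    aln, _ = simulate_alignment(tree, lg_model(), GammaRates(2.0, 4), 1000, seed=13)
    return tree, aln


class TestBootstrapSupport:
    def test_identical_seed_identical_output(self, lg, treelike_alignment):
        _, aln = treelike_alignment
        s1 = bootstrap_support(aln, lg, n_replicates=20, seed=4)
        s2 = bootstrap_support(aln, lg, n_replicates=20, seed=4)
        assert s1 == s2

    def test_true_splits_strongly_supported(self, lg, treelike_alignment):
        tree, aln = treelike_alignment
        support = bootstrap_support(aln, lg, n_replicates=50, seed=4)
        for split in tree.splits_of():
            assert support.get(split, 0.0) >= 95.0

    def test_support_is_replicate_fraction(self, lg, treelike_alignment):
        _, aln = treelike_alignment
        support = bootstrap_support(aln, lg, n_replicates=8, seed=1)
        for value in support.values():
            assert value == pytest.approx(100.0 * round(value * 8 / 100) / 8)

    def test_manual_tally_on_five_taxon_toy(self, lg):
        """Support equals the hand count of replicate trees displaying a split."""
        from fslb.inference import impute_undefined, neighbor_joining

        tree = PhyloTree.from_newick("(((A:0.2,B:0.2):0.3,C:0.4):0.05,(D:0.3,E:0.3):0.2);")
        aln, _ = simulate_alignment(tree, lg, GammaRates(1.0, 1), 120, seed=21)
        n_reps, seed = 12, 77
        support = bootstrap_support(aln, lg, n_replicates=n_reps, seed=seed)

        engine = DistanceEngine(lg)
        prepared = engine.prepare(aln)
        rng = np.random.default_rng(seed)
        tallies = {}
        for _ in range(n_reps):
            draws = rng.integers(0, aln.n_sites, aln.n_sites)
            weights = np.bincount(draws, minlength=aln.n_sites).astype(float)
            D = impute_undefined(engine.matrix(prepared, site_weights=weights))
            rep_tree = neighbor_joining(D, labels=aln.taxa)
            for split in rep_tree.splits_of():
                tallies[split] = tallies.get(split, 0) + 1
        assert support == {s: 100.0 * c / n_reps for s, c in tallies.items()}

    def test_replicate_splits_mutually_compatible(self, lg, treelike_alignment):
        from fslb import splits_compatible

        _, aln = treelike_alignment
        engine = DistanceEngine(lg)
        prepared = engine.prepare(aln)
        rng = np.random.default_rng(2)
        draws = rng.integers(0, aln.n_sites, aln.n_sites)
        weights = np.bincount(draws, minlength=aln.n_sites).astype(float)
        splits = list(
            neighbor_joining(impute_undefined(engine.matrix(prepared, site_weights=weights)),
                             labels=aln.taxa).splits_of()
        )
        for a, b in itertools.combinations(splits, 2):
            assert splits_compatible(a, b)

    def test_cell_seed_deterministic_and_distinct(self):
        assert cell_seed(5, 1, 200) == cell_seed(5, 1, 200)
        assert cell_seed(5, 1, 200) != cell_seed(5, 2, 200)
        assert cell_seed(5, 1, 200) != cell_seed(6, 1, 200)


class TestCladeSupport:
    def test_singleton_intersection_trivial_100(self):
        clade = CladeDefinition("c", {"A", "B"})
        result = clade_support({}, clade, retained={"A", "C", "D"})
        assert (result.value, result.status) == (100.0, "trivial")

    def test_empty_intersection_undefined(self):
        clade = CladeDefinition("c", {"A", "B"})
        result = clade_support({}, clade, retained={"C", "D", "E"})
        assert result.status == "undefined"
        assert result.value is None

    def test_absent_clade_scores_zero(self):
        clade = CladeDefinition("c", {"A", "B"})
        split_map = {Bipartition({"A", "C"}, {"B", "D"}): 80.0}
        result = clade_support(split_map, clade, retained={"A", "B", "C", "D"})
        assert (result.value, result.status) == (0.0, "ok")

    def test_three_of_four_trees_gives_75(self):
        trees = [
            "((A:1,B:1):1,(C:1,D:1):1);",
            "((A:1,B:1):1,(C:1,D:1):1);",
            "((A:1,B:1):1,(C:1,D:1):1);",
            "((A:1,C:1):1,(B:1,D:1):1);",
        ]
        tally = {}
        for nwk in trees:
            for split in PhyloTree.from_newick(nwk).splits_of():
                tally[split] = tally.get(split, 0) + 1
        split_map = {s: 100.0 * c / 4 for s, c in tally.items()}
        result = clade_support(split_map, CladeDefinition("ab", {"A", "B"}), retained="ABCD")
        assert result.value == pytest.approx(75.0)


class TestConflictScreen:
    REF = "(((A:1,B:1)95:1,C:1):1,(D:1,E:1)90:1);"

    def test_identical_topology_reports_nothing(self):
        ref = PhyloTree.from_newick(self.REF)
        gene = PhyloTree.from_newick("(((A:2,B:2)88:2,C:2):2,(D:2,E:2)91:2);")
        assert conflicting_bipartitions(gene, ref, threshold=70.0) == []

    def test_supported_conflict_reported(self):
        ref = PhyloTree.from_newick(self.REF)
        gene = PhyloTree.from_newick("(((A:1,C:1)90:1,B:1):1,(D:1,E:1)80:1);")
        found = conflicting_bipartitions(gene, ref, threshold=70.0)
        assert len(found) == 1
        split, support, ref_split = found[0]
        assert support == 90.0
        assert split == Bipartition({"A", "C"}, {"B", "D", "E"})
        assert ref_split == Bipartition({"A", "B"}, {"C", "D", "E"})

    def test_weak_conflict_suppressed(self):
        ref = PhyloTree.from_newick(self.REF)
        gene = PhyloTree.from_newick("(((A:1,C:1)65:1,B:1):1,(D:1,E:1)80:1);")
        assert conflicting_bipartitions(gene, ref, threshold=70.0) == []

    def test_threshold_is_strict(self):
        ref = PhyloTree.from_newick(self.REF)
        gene = PhyloTree.from_newick("(((A:1,C:1)70:1,B:1):1,(D:1,E:1)80:1);")
        assert conflicting_bipartitions(gene, ref, threshold=70.0) == []

    def test_gene_tree_restricted_to_shared_taxa(self):
        ref = PhyloTree.from_newick(self.REF)
        gene = PhyloTree.from_newick("((((A:1,C:1)90:1,B:1):1,D:1):1,(F:1,G:1)99:1);")
        found = conflicting_bipartitions(gene, ref, threshold=70.0)
        assert [s.restrict({"A", "B", "C", "D"}) is not None for s, _, _ in found]
        assert all("F" not in side for s, _, _ in found for side in s.sides)

    def test_too_few_shared_taxa_rejected(self):
        ref = PhyloTree.from_newick(self.REF)
        gene = PhyloTree.from_newick("((A:1,B:1)90:1,(X:1,Y:1)90:1);")
        with pytest.raises(ValueError):
            conflicting_bipartitions(gene, ref, threshold=70.0)


class TestRelabelEquivariance:
    def test_support_surface_invariant_to_taxon_relabelling(self, lg):
        """Renaming taxa renames surface inputs but not support values."""
        from fslb import GridConfig, build_grid, support_surface

        tree = PhyloTree.from_newick(
            "(((A:0.1,B:0.1):0.4,(C:0.1,D:0.1):0.4):0.05,(E:0.1,F:0.1):0.4);"
        )
        aln, _ = simulate_alignment(tree, lg, GammaRates(1.0, 2), 300, seed=3)
        config = GridConfig(k=3, n_remove_taxa=1, site_step=100, max_sites_removed=100,
                            n_bootstrap=10, seed=9)
        mapping = {t: f"taxon_{t}" for t in aln.taxa}

        manifest = build_grid(aln, tree, config, gamma=GammaRates(1.0, 4))
        surf = support_surface(manifest, CladeDefinition("ab", {"A", "B"}), lg)

        renamed_aln = Alignment([mapping[t] for t in aln.taxa], aln.data, aln.site_indices)
        renamed_tree = PhyloTree.from_newick(tree.to_newick())
        for node in renamed_tree.preorder():
            if node.is_leaf:
                node.label = mapping[node.label]
        manifest2 = build_grid(renamed_aln, renamed_tree, config, gamma=GammaRates(1.0, 4))
        surf2 = support_surface(
            manifest2, CladeDefinition("ab", {"taxon_A", "taxon_B"}), lg
        )
        assert np.allclose(surf.values, surf2.values, equal_nan=True)
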