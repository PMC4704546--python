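import numpy as np
import pytest

import barcodeval as bv
from barcodeval.tree_eval import node_support, tree_bipartitions
from _oracles import (
    best_ls_tree,
    dendropy_edge_lengths,
    dendropy_splits,
    random_additive_matrix,
)


def dmatrix(labels, D, species=None):
    n = len(labels)
    return bv.DistanceMatrix(
        list(labels),
        species or ["s"] * n,
        np.asarray(D, dtype=float),
        np.full((n, n), 100, dtype=np.int64),
    )


class TestNeighborJoining:
    def test_four_taxon_additive_matrix(self):
        # d(AB)=2, d(CD)=2, cross pairs 3 -> split AB|CD, tips 1, internal 1
        D = [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]]
        tree = bv.neighbor_joining(dmatrix("ABCD", D))
        lengths = dendropy_edge_lengths(tree, list("ABCD"))
        key_ab = (2, ("A", "B"))
        assert key_ab in lengths  # the AB|CD split
        assert lengths[key_ab] == pytest.approx(1.0)
        for leaf in "ABCD":
            assert lengths[(1, (leaf,))] == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        D = [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]
        tree = bv.neighbor_joining(dmatrix("ABC", D))
        lengths = dendropy_edge_lengths(tree, list("ABC"))
        assert lengths[(1, ("A",))] == pytest.approx(0.1)
        assert lengths[(1, ("B",))] == pytest.approx(0.3)
        assert lengths[(1, ("C",))] == pytest.approx(0.5)

    def test_ultrametric_cherries_match_single_linkage_split(self):
        # two cherries at depth 1 within, 4 across: NJ must separate them
        D = [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]]
        tree = bv.neighbor_joining(dmatrix("ABCD", D))
        assert (2, ("A", "B")) in dendropy_splits(tree, list("ABCD"))

    def test_recovers_random_additive_trees_vs_ls_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 7))
            taxa, D, true_splits, true_lengths = random_additive_matrix(rng, n)
            tree = bv.neighbor_joining(dmatrix(taxa, D))
            assert dendropy_splits(tree, taxa) == true_splits
            got = dendropy_edge_lengths(tree, taxa)
            rss, ls_splits, ls_lengths = best_ls_tree(taxa, D)
            assert ls_splits == true_splits and rss < 1e-18
            for key, ln in true_lengths.items():
                assert got[key] == pytest.approx(ln, abs=1e-9)
                assert ls_lengths[key] == pytest.approx(ln, abs=1e-9)

    def test_undefined_distance_rejected_with_guidance(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        m = dmatrix("ABC", D)
        with pytest.raises(ValueError, match="impute|remove"):
            bv.neighbor_joining(m)

    def test_negative_branches_clamped(self):
        # a strongly non-additive matrix that produces a negative NJ branch
        D = [[0, 0.1, 0.5, 0.55], [0.1, 0, 0.55, 0.5], [0.5, 0.55, 0, 0.01], [0.55, 0.5, 0.01, 0]]
        tree = bv.neighbor_joining(dmatrix("ABCD", D))
        for node in tree.preorder_node_iter():
            if node.edge.length is not None:
                assert node.edge.length >= 0


class TestBootstrap:
    def test_strong_split_gets_full_support(self):
        aln = bv.MarkerAlignment(
            "m",
            ["a1", "a2", "b1", "b2"],
            ["A", "A", "B", "B"],
            ["A" * 100, "A" * 100, "T" * 100, "T" * 100],
        )
        tree = bv.bootstrap_support(aln, n_reps=10, seed=1)
        sups = [node_support(n) for n in tree.preorder_node_iter()
                if not n.is_leaf() and n.parent_node is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_leaf_support_is_100_by_convention(self):
        aln = bv.MarkerAlignment(
            "m", ["a", "b", "c"], ["A", "B", "C"], ["AAAA", "AATT", "TTTT"]
        )
        tree = bv.bootstrap_support(aln, n_reps=5, seed=0)
        leaf = next(tree.leaf_node_iter())
        assert node_support(leaf) == 100.0

    def test_same_seed_reproduces_supports(self, toy_alignment):
        t1 = bv.bootstrap_support(toy_alignment, n_reps=20, seed=7)
        t2 = bv.bootstrap_support(toy_alignment, n_reps=20, seed=7)
        assert bv.write_newick(t1) == bv.write_newick(t2)

    def test_supports_invariant_to_leaf_input_order(self, rng):
        from conftest import random_alignment

        aln = random_alignment(rng, n_rows=6, n_cols=40, missing_frac=0.0)
        order = list(rng.permutation(6))
        shuffled = bv.MarkerAlignment(
            "m",
            [aln.ids[i] for i in order],
            [aln.species[i] for i in order],
            [aln.seqs[i] for i in order],
        )
        t1 = bv.bootstrap_support(aln, n_reps=30, seed=3)
        t2 = bv.bootstrap_support(shuffled, n_reps=30, seed=3)
        assert t1.support_map == t2.support_map

    def test_support_counts_bounded_by_replicates(self, toy_alignment):
        tree = bv.bootstrap_support(toy_alignment, n_reps=25, seed=2)
        assert tree.bootstrap_retained + tree.bootstrap_dropped == 25
        for sup in tree.support_map.values():
            assert 0 <= sup <= 100


class TestRooting:
    def test_root_on_single_leaf(self):
        tree = bv.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = bv.root_tree(tree, {"A"})
        children = rooted.seed_node.child_nodes()
        sides = [
            {l.taxon.label for l in c.leaf_iter()} for c in children
        ]
        assert {"A"} in sides

    def test_root_on_cherry(self):
        tree = bv.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:2);")
        rooted = bv.root_tree(tree, {"A", "B"})
        sides = [
            {l.taxon.label for l in c.leaf_iter()}
            for c in rooted.seed_node.child_nodes()
        ]
        assert {"A", "B"} in sides

    def test_scattered_outgroup_rejected(self):
        tree = bv.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.raises(ValueError, match="monophyletic"):
            bv.root_tree(tree, {"A", "B"})

    def test_supports_survive_rerooting(self):
        tree = bv.read_newick("((A:1,B:1)95:1,(C:1,D:1)80:1,E:2);")
        rooted = bv.root_tree(tree, {"E"})
        labels = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.label
            for n in rooted.preorder_node_iter()
            if not n.is_leaf()
        }
        assert labels.get(frozenset("AB")) == "95"
        assert labels.get(frozenset("CD")) == "80"


class TestNewickRoundTrip:
    def test_topology_lengths_and_supports_preserved(self, tmp_path):
        src = "((A:1.5,B:2.25)95:0.5,(C:1,D:1)80:0.75,E:3);"
        tree = bv.read_newick(src)
        p = tmp_path / "t.nwk"
        bv.write_newick(tree, p)
        back = bv.read_newick(str(p))
        assert dendropy_edge_lengths(back, list("ABCDE")) == dendropy_edge_lengths(
            tree, list("ABCDE")
        )
        sups = {
            n.label
            for n in back.preorder_node_iter()
            if not n.is_leaf() and n.label
        }
        assert sups == {"95", "80"}


class TestSpeciesSpecificClusters:
    SPECIES = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "Out": "O"}

    def test_supported_and_unsupported_clusters(self):
        tree = bv.read_newick("((A1:1,A2:1)95:1,((B1:1,B2:1)60:1,Out:1):1);")
        tree.is_rooted = True
        rep = bv.species_specific_clusters(tree, self.SPECIES, cutoff=70)
        per = rep.per_species.set_index("species")
        assert bool(per.loc["A", "species_specific_cluster"])
        assert per.loc["B", "monophyletic"] and not per.loc["B", "species_specific_cluster"]
        assert rep.n_counted == 2
        assert rep.percent_species_specific == pytest.approx(50.0)

    def test_all_singletons_not_applicable(self):
        tree = bv.read_newick("((A1:1,B1:1)99:1,(C1:1,D1:1)99:1);")
        species = {x: x[0] for x in ["A1", "B1", "C1", "D1"]}
        rep = bv.species_specific_clusters(tree, species, cutoff=70)
        assert rep.n_counted == 0
        assert np.isnan(rep.percent_species_specific)

    def test_split_species_never_monophyletic(self):
        tree = bv.read_newick("((A1:1,B1:1)99:1,((A2:1,B2:1)99:1,Out:1)99:1);")
        tree.is_rooted = True
        rep = bv.species_specific_clusters(tree, self.SPECIES, cutoff=0)
        per = rep.per_species.set_index("species")
        assert not per.loc["A", "monophyletic"]

    def test_every_species_a_supported_cherry_gives_100(self):
        tree = bv.read_newick("((A1:1,A2:1)90:1,((B1:1,B2:1)88:1,Out:1):1);")
        tree.is_rooted = True
        rep = bv.species_specific_clusters(tree, self.SPECIES, cutoff=70)
        assert rep.percent_species_specific == pytest.approx(100.0)
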