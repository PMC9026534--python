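"""Neighbor joining, lineage cutting and family assignment."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from herdgen.families import (
    assign_families,
    cut_lineages,
    neighbor_joining,
    suggest_k,
)
from herdgen.relatedness import RelationshipMatrix, ibs_distance, vanraden_g
from herdgen.sim import simulate_family_dataset

from oracles import random_additive_matrix


class TestNeighborJoining:
    def test_two_leaves_single_edge(self):
        t = neighbor_joining(np.array([[0.0, 3.5], [3.5, 0.0]]), ["a", "b"])
        assert t.leaf_path_lengths()[0, 1] == pytest.approx(3.5)

    def test_three_leaves_closed_form(self):
        """Star tree branch lengths solve the three path equations exactly."""
        d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        t = neighbor_joining(d, ["a", "b", "c"])
        paths = t.leaf_path_lengths()
        assert np.allclose(paths, d)
        # la = (dab + dac - dbc)/2 = 3, lb = 2, lc = 6
        lengths = sorted(e.length for e in t.edges)
        assert lengths == pytest.approx([2.0, 3.0, 6.0])

    @pytest.mark.parametrize("n_leaves", [4, 6, 8, 10, 12])
    def test_additive_matrix_recovery(self, n_leaves):
        """NJ reproduces the generating tree's distances on additive input."""
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(8):
            d = random_additive_matrix(n_leaves, rng)
            t = neighbor_joining(d)
            assert np.allclose(t.leaf_path_lengths(), d, atol=1e-9)

    def test_topology_matches_external_nj(self):
        """Same unrooted topology as an independent NJ implementation."""
        import skbio

        rng = np.random.default_rng(77)
        d = random_additive_matrix(8, rng)
        d = (d + d.T) / 2  # remove float-summation asymmetry for skbio
        names = [f"L{i}" for i in range(8)]
        ours = dendropy.Tree.get(
            data=neighbor_joining(d, names).newick(), schema="newick"
        )
        dm = skbio.DistanceMatrix(d, ids=names)
        theirs = dendropy.Tree.get(
            data=str(skbio.tree.nj(dm)), schema="newick",
            taxon_namespace=ours.taxon_namespace,
        )
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert (
            dendropy.calculate.treecompare.symmetric_difference(ours, theirs)
            == 0
        )

    def test_newick_round_trips_through_dendropy(self):
        rng = np.random.default_rng(3)
        d = random_additive_matrix(7, rng)
        t = neighbor_joining(d)
        parsed = dendropy.Tree.get(data=t.newick(), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(
            t.leaf_names
        )
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in parsed.taxon_namespace}
        for i in range(7):
            for j in range(i + 1, 7):
                assert pdm.distance(taxa[f"L{i}"], taxa[f"L{j}"]) == pytest.approx(
                    d[i, j], abs=1e-6
                )

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestCutLineages:
    @pytest.fixture
    def tree(self):
        rng = np.random.default_rng(9)
        return neighbor_joining(random_additive_matrix(6, rng))

    def test_k_one_single_lineage(self, tree):
        assert set(cut_lineages(tree, 1).values()) == {1}

    def test_k_equals_leaf_count_singletons(self, tree):
        out = cut_lineages(tree, 6)
        assert sorted(out.values()) == [1, 2, 3, 4, 5, 6]

    def test_k_out_of_range_rejected(self, tree):
        with pytest.raises(ValueError):
            cut_lineages(tree, 0)
        with pytest.raises(ValueError):
            cut_lineages(tree, 7)

    def test_two_planted_families_recovered(self):
        """Between-family distance ≫ within: k=2 reproduces the labels."""
        rng = np.random.default_rng(21)
        n = 10
        labels = [0] * 5 + [1] * 5
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base = 0.05 if labels[i] == labels[j] else 1.0
                d[i, j] = d[j, i] = base + rng.uniform(0, 0.01)
        tree = neighbor_joining(d)
        cut = cut_lineages(tree, 2)
        found = [cut[f"L{i}"] for i in range(n)]
        assert adjusted_rand_score(labels, found) == 1.0

    def test_invariant_to_leaf_relabeling(self):
        rng = np.random.default_rng(31)
        d = random_additive_matrix(7, rng)
        perm = rng.permutation(7)
        names = [f"L{i}" for i in range(7)]
        cut1 = cut_lineages(neighbor_joining(d, names), 3)
        cut2 = cut_lineages(
            neighbor_joining(d[np.ix_(perm, perm)], [names[i] for i in perm]), 3
        )
        # same partition of leaf names, up to lineage renumbering
        part1 = {}
        for leaf, lin in cut1.items():
            part1.setdefault(lin, set()).add(leaf)
        part2 = {}
        for leaf, lin in cut2.items():
            part2.setdefault(lin, set()).add(leaf)
        assert set(map(frozenset, part1.values())) == set(
            map(frozenset, part2.values())
        )

    def test_suggest_k_finds_planted_gap(self):
        rng = np.random.default_rng(41)
        n = 12
        labels = [0] * 4 + [1] * 4 + [2] * 4
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base = 0.05 if labels[i] == labels[j] else 2.0
                d[i, j] = d[j, i] = base + rng.uniform(0, 0.01)
        assert suggest_k(neighbor_joining(d)) == 3


class TestAssignFamilies:
    def make_g(self, ids, values):
        return RelationshipMatrix(ids, np.asarray(values, float), "G")

    def test_unique_maximum(self):
        g = self.make_g(
            ["b1", "b2", "s1"],
            [[1, 0, 0.5], [0, 1, -0.1], [0.5, -0.1, 1]],
        )
        fam = assign_families(g, {"b1": 3, "b2": 1})
        assert fam.family_of_sample["s1"] == 3

    def test_below_threshold_goes_to_unrelated_family(self):
        g = self.make_g(
            ["b1", "b2", "s1"],
            [[1, 0, 0.05], [0, 1, 0.02], [0.05, 0.02, 1]],
        )
        fam = assign_families(g, {"b1": 1, "b2": 2}, threshold=0.1)
        assert fam.family_of_sample["s1"] == fam.unrelated_family == 3

    def test_tie_breaks_to_lowest_lineage(self):
        g = self.make_g(
            ["b1", "b2", "s1"],
            [[1, 0, 0.4], [0, 1, 0.4], [0.4, 0.4, 1]],
        )
        fam = assign_families(g, {"b1": 5, "b2": 2})
        assert fam.family_of_sample["s1"] == 2

    def test_missing_boar_rejected(self):
        g = self.make_g(["s1"], [[1.0]])
        with pytest.raises(ValueError):
            assign_families(g, {"b1": 1})


class TestEndToEndFamilyRecovery:
    def test_planted_families_ari(self):
        """Pedigree families with diverged founders recovered at ARI >= 0.9."""
        ds, truth = simulate_family_dataset(
            n_families=4,
            boars_per_family=3,
            sows_per_family=6,
            n_generations=2,
            inbred_loop_fraction=0.1,
            n_chroms=6,
            n_markers_per_chrom=300,
            founder_fst=0.15,
            missing_rate=0.02,
            seed=99,
        )
        ibs = ibs_distance(ds)
        g = vanraden_g(ds)
        boars = [i for i, s in enumerate(ds.samples) if s.group_label == "boar"]
        boar_ids = [ds.samples[i].sample_id for i in boars]
        tree = neighbor_joining(ibs.values[np.ix_(boars, boars)], boar_ids)
        lineages = cut_lineages(tree, 4)
        fam = assign_families(g, lineages, threshold=0.1)
        ids = ds.sample_ids
        found = [fam.family_of_sample[i] for i in ids]
        true = [truth.true_family[i] for i in ids]
        assert adjusted_rand_score(true, found) >= 0.9
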