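"""Distances, neighbor joining, bootstrap, rooting, newick."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lrcpipe import phylo as P

from .oracles import mask_oracle


def random_additive_tree(n, rng):
    nodes = [P.Node(label=f"T{i}", length=rng.uniform(0.1, 1.0))
             for i in range(n)]
    while len(nodes) > 3:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(P.Node(children=[a, b],
                            length=rng.uniform(0.1, 1.0)))
    return P.PhyloTree(P.Node(children=nodes))


def tree_metric_matrix(tree):
    pl = tree.path_lengths()
    labels = sorted(tree.leaf_labels)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pl[(labels[i], labels[j])]
    return P.DistanceMatrix(labels, m)


class TestPairwiseDeletion:
    def test_clean_pair_keeps_all_sites(self):
        assert P.pairwise_deletion_mask("ACGT", "TGCA") == [0, 1, 2, 3]

    def test_gap_and_ambiguity_sites_removed(self):
        # site 2 is a gap, site 3 an ambiguity code: both excluded
        assert P.pairwise_deletion_mask("AC-GT", "ACGNT") == [0, 1, 4]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGTN-", min_size=1, max_size=30),
           st.text(alphabet="ACGTN-", min_size=1, max_size=30))
    def test_matches_per_site_filter(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert P.pairwise_deletion_mask(a, b) == mask_oracle(a, b, "ACGT")


class TestTamura3:
    def test_identical_sequences_distance_zero(self):
        d, c = P.tamura3_distance("ACGTACGT", "ACGTACGT")
        assert d == 0.0 and c.P == 0.0 and c.Q == 0.0

    def test_constructed_pqc_matches_direct_formula(self):
        # 100 usable sites with P=0.10 (C<->T), Q=0.05 (A<->T), theta=0.40
        si = "C" * 10 + "A" * 5 + "G" * 35 + "A" * 50
        sj = "T" * 10 + "T" * 5 + "G" * 35 + "A" * 50
        d, c = P.tamura3_distance(si, sj)
        assert (c.P, c.Q, c.theta) == (0.10, 0.05, 0.40)
        h = 2 * 0.4 * 0.6
        expect = -h * math.log(1 - 0.10 / h - 0.05) \
            - 0.5 * (1 - h) * math.log(1 - 2 * 0.05)
        assert d == pytest.approx(expect, abs=1e-15)

    def test_reduces_to_kimura_2p_at_half_gc(self):
        # pooled G+C content exactly 1/2
        si = "C" * 10 + "A" * 5 + "G" * 45 + "A" * 40
        sj = "T" * 10 + "T" * 5 + "G" * 45 + "A" * 40
        d, c = P.tamura3_distance(si, sj)
        assert c.theta == 0.5
        k2p = -0.5 * math.log(1 - 2 * c.P - c.Q) \
            - 0.25 * math.log(1 - 2 * c.Q)
        assert d == pytest.approx(k2p, abs=1e-15)

    def test_reduces_to_jukes_cantor_with_symmetric_changes(self):
        # theta = 1/2 and all three substitution types equally frequent
        # (transversions twice transitions): with p the total difference
        # proportion, JC is -(3/4) ln(1 - 4p/3)
        si = "A" * 24 + "C" * 24 + "G" * 24 + "T" * 24
        sj = ("G" + "C" + "T" + "A" * 21
              + "T" + "A" + "G" + "C" * 21
              + "A" + "C" + "T" + "G" * 21
              + "C" + "A" + "G" + "T" * 21)
        d, c = P.tamura3_distance(si, sj)
        assert c.theta == 0.5 and c.Q == pytest.approx(2 * c.P)
        p = c.P + c.Q
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert d == pytest.approx(jc, abs=1e-12)

    def test_saturation_is_flagged_undefined(self):
        d, _ = P.tamura3_distance("ACACACAC", "CACACACA")
        assert math.isnan(d)

    def test_gap_only_pair_undefined(self):
        d, c = P.tamura3_distance("----", "ACGT")
        assert math.isnan(d) and c.n_usable == 0


class TestPDistance:
    def test_identical_is_zero(self):
        assert P.p_distance("PEPTIDE", "PEPTIDE") == 0.0

    def test_one_difference_over_ten(self):
        assert P.p_distance("AAAAAAAAAA", "AAAAAAAAAW") == 0.1

    def test_gaps_excluded_from_denominator(self):
        assert P.p_distance("AA-AA", "AAWAW") == 0.25


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        dm = P.DistanceMatrix(["A", "B", "C"],
                              [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = P.neighbor_joining(dm)
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_exact_on_additive_matrices(self):
        rng = random.Random(7)
        for _ in range(30):
            true = random_additive_tree(rng.randint(4, 8), rng)
            dm = tree_metric_matrix(true)
            rec = P.neighbor_joining(dm)
            out = rec.path_lengths()
            for pair, d in true.path_lengths().items():
                assert out[pair] == pytest.approx(d, abs=1e-9)

    def test_deterministic_under_taxon_permutation(self):
        rng = random.Random(9)
        true = random_additive_tree(6, rng)
        dm = tree_metric_matrix(true)
        perm = list(range(6))
        rng.shuffle(perm)
        labels2 = [dm.labels[i] for i in perm]
        m2 = dm.matrix[np.ix_(perm, perm)]
        t1 = P.neighbor_joining(dm)
        t2 = P.neighbor_joining(P.DistanceMatrix(labels2, m2))
        assert set(t1.bipartitions()) == set(t2.bipartitions())
        assert t1.path_lengths() == pytest.approx(t2.path_lengths())

    def test_matches_dendropy_on_random_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = random.Random(11)
        true = random_additive_tree(7, rng)
        dm = tree_metric_matrix(true)
        csv = "," + ",".join(dm.labels) + "\n"
        for label, row in zip(dm.labels, dm.matrix):
            csv += label + "," + ",".join(map(str, row)) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=",")
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        want = {frozenset(str(t) for t in b.leafset_taxa(dtree.taxon_namespace))
                for b in dtree.bipartition_encoding}
        ref = min(dm.labels)
        all_leaves = frozenset(dm.labels)
        norm_want = set()
        for side in want:
            side = frozenset(l.strip("'") for l in side)
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                norm_want.add(side)
        mine = set(P.neighbor_joining(dm).bipartitions())
        assert mine == norm_want

    def test_undefined_entries_refused(self):
        m = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(ValueError, match="undefined"):
            P.neighbor_joining(P.DistanceMatrix(["A", "B", "C"], m))

    def test_fewer_than_three_taxa_refused(self):
        with pytest.raises(ValueError):
            P.neighbor_joining(P.DistanceMatrix(["A", "B"],
                                                [[0, 1], [1, 0]]))


class TestBootstrap:
    def toy_msa(self):
        return P.Msa(["A", "B", "C", "D"],
                     ["ACGTACGTACGTACGTAAAA",
                      "ACGTACGTACGTACGTAAAT",
                      "TGCAACGTACGTACGTAAAA",
                      "TGCAACGAACGTACGTAAAA"])

    def test_seed_reproducibility(self):
        r1 = P.bootstrap_support(self.toy_msa(), 10, seed=5)
        r2 = P.bootstrap_support(self.toy_msa(), 10, seed=5)
        assert r1.split_counts == r2.split_counts
        assert P.write_newick(r1.tree) == P.write_newick(r2.tree)

    def test_invariant_columns_give_full_support(self):
        # one column pattern repeated: resampling cannot change the
        # alignment, so every full-data bipartition is supported at 100
        msa = P.Msa(["A", "B", "C", "D"],
                    ["A" * 20, "A" * 20, "C" * 20, "C" * 20])
        res = P.bootstrap_support(msa, 20, seed=1, distance_kind="p")
        supports = [n.support for n in res.tree.bipartitions().values()]
        assert supports and all(s == 100 for s in supports)

    def test_supports_within_bounds(self):
        res = P.bootstrap_support(self.toy_msa(), 25, seed=3)
        for node in res.tree.bipartitions().values():
            assert 0 <= node.support <= 100

    def test_consensus_excludes_minority_branches(self):
        res = P.bootstrap_support(self.toy_msa(), 50, seed=2,
                                  consensus=True)
        cons_splits = res.consensus.tree_splits \
            if hasattr(res.consensus, "tree_splits") \
            else set(res.consensus.bipartitions())
        accepted = res.n_replicates - res.n_dropped
        for split in cons_splits:
            assert res.split_counts.get(split, 0) / accepted > 0.5

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            P.bootstrap_support(self.toy_msa(), 0, seed=1)


class TestRooting:
    def four_taxon_tree(self):
        return P.neighbor_joining(P.DistanceMatrix(
            ["A", "B", "C", "D"],
            [[0, 2, 9, 9], [2, 0, 9, 9], [9, 9, 0, 2], [9, 9, 2, 0]]))

    def test_single_outgroup_leaf(self):
        rooted = P.root_tree(self.four_taxon_tree(), ["D"])
        sides = sorted(sorted(c.leaf_labels())
                       for c in rooted.root.children)
        assert sides == [["A", "B", "C"], ["D"]]

    def test_outgroup_clade(self):
        rooted = P.root_tree(self.four_taxon_tree(), ["C", "D"])
        sides = {frozenset(c.leaf_labels()) for c in rooted.root.children}
        assert frozenset(["C", "D"]) in sides

    def test_rooting_preserves_ingroup_bipartitions(self):
        rng = random.Random(13)
        true = random_additive_tree(7, rng)
        dm = tree_metric_matrix(true)
        unrooted = P.neighbor_joining(dm)
        before = set(unrooted.bipartitions())
        outgroup_split = sorted(before, key=len)[0]
        rooted = P.root_tree(unrooted, sorted(outgroup_split))
        after = set(rooted.bipartitions())
        assert before <= after | {outgroup_split}

    def test_all_taxa_outgroup_is_error(self):
        with pytest.raises(ValueError):
            P.root_tree(self.four_taxon_tree(), ["A", "B", "C", "D"])

    def test_non_monophyletic_outgroup_is_error(self):
        with pytest.raises(ValueError, match="monophyletic"):
            P.root_tree(self.four_taxon_tree(), ["A", "C"])


class TestNewick:
    def test_two_leaf_shape(self):
        tree = P.PhyloTree(P.Node(children=[
            P.Node(label="A", length=1.0), P.Node(label="B", length=2.0)]))
        assert P.write_newick(tree) == "(A:1,B:2);"

    def test_label_quoting(self):
        tree = P.PhyloTree(P.Node(children=[
            P.Node(label="seq one", length=1.0),
            P.Node(label="B", length=2.0)]))
        assert P.write_newick(tree) == "('seq one':1,B:2);"

    def test_round_trip_against_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = random.Random(17)
        for _ in range(10):
            tree = random_additive_tree(rng.randint(4, 8), rng)
            text = P.write_newick(tree)
            parsed = dendropy.Tree.get(data=text, schema="newick")
            assert {l.taxon.label for l in parsed.leaf_node_iter()} == \
                set(tree.leaf_labels)
            pdm = parsed.phylogenetic_distance_matrix()
            mine = tree.path_lengths()
            for t1 in parsed.taxon_namespace:
                for t2 in parsed.taxon_namespace:
                    if t1.label < t2.label:
                        got = pdm.path_edge_count(t1, t2)  # presence check
                        d = pdm.distance(t1, t2)
                        assert d == pytest.approx(
                            mine[(t1.label, t2.label)], rel=1e-6)
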