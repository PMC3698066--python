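import math

import dendropy
import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from phagemarker.phylo import (
    DistanceMatrix,
    bootstrap_consensus,
    clade_recovery,
    ffp_distance,
    ffp_distance_matrix,
    ffp_profile,
    gsi,
    matching_splits,
    ms_percent_of_star,
    nj_tree,
    nontrivial_splits,
    read_newick,
    star_tree,
    write_newick,
)
from phagemarker.seqcore import LabelTable, SeqRecord, revcomp

from conftest import random_dna


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestFFProfile:
    def test_hand_count(self):
        p = ffp_profile("ACGAC", 2)
        assert p.counts == {"AC": 2, "CG": 1, "GA": 1}
        assert p.total == 4

    def test_total_is_window_count(self):
        rng = np.random.default_rng(60)
        s = random_dna(rng, 500)
        p = ffp_profile(s, 20)
        assert p.total == 481

    def test_ambiguous_windows_skipped(self):
        p = ffp_profile("ACGTNACGT", 4)
        # windows overlapping the N are dropped
        assert p.total == 2
        assert set(p.counts) == {"ACGT"}

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ffp_profile("ACG", 4)

    def test_strand_asymmetry(self):
        s = "AACCGGTTAACC"
        p = ffp_profile(s, 4)
        q = ffp_profile(revcomp(s), 4)
        assert p.counts != q.counts


class TestFFPDistance:
    def test_identical_profiles_zero(self):
        rng = np.random.default_rng(61)
        s = random_dna(rng, 300)
        assert ffp_distance(ffp_profile(s, 10), ffp_profile(s, 10)) == 0.0

    def test_disjoint_profiles_ln2(self):
        d = ffp_distance(ffp_profile("A" * 50, 5), ffp_profile("C" * 50, 5))
        assert d == pytest.approx(math.log(2))

    def test_matches_scipy_oracle(self):
        """Shared-feature summation equals the dense Jensen-Shannon formula."""
        rng = np.random.default_rng(62)
        for _ in range(5):
            a = ffp_profile(random_dna(rng, 200), 3)
            b = ffp_profile(random_dna(rng, 150), 3)
            union = sorted(set(a.counts) | set(b.counts))
            pv = np.array([a.counts.get(w, 0) for w in union]) / a.total
            qv = np.array([b.counts.get(w, 0) for w in union]) / b.total
            want = jensenshannon(pv, qv, base=math.e) ** 2
            assert ffp_distance(a, b) == pytest.approx(want, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(63)
        a = ffp_profile(random_dna(rng, 120), 4)
        b = ffp_profile(random_dna(rng, 120), 4)
        assert ffp_distance(a, b) == pytest.approx(ffp_distance(b, a))

    def test_mismatched_feature_length_rejected(self):
        with pytest.raises(ValueError):
            ffp_distance(ffp_profile("ACGTACGT", 3), ffp_profile("ACGTACGT", 4))


class TestNJ:
    def test_three_taxa_closed_form(self):
        # d(a,b)=5, d(a,c)=9, d(b,c)=10 -> leaf branches a=2, b=3, c=7;
        # the tree must reproduce the input distances as path lengths
        D = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        )
        tree = nj_tree(D)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(5.0)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(9.0)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(10.0)

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):2,(c:2,d:4)) -> additive distances
        D = DistanceMatrix(
            list("abcd"),
            np.array(
                [[0, 3, 7, 9], [3, 0, 8, 10], [7, 8, 0, 6], [9, 10, 6, 0]], float
            ),
        )
        tree = nj_tree(D)
        splits = nontrivial_splits(tree)
        assert len(splits) == 1
        assert frozenset({"a", "b"}) in splits[0]

    def test_random_additive_trees_recovered(self):
        """NJ reproduces the generating topology from additive distances."""
        import random as pyrandom

        rng = np.random.default_rng(64)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            sim = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                rng=pyrandom.Random(int(rng.integers(1, 2**16))),
            )
            for i, lf in enumerate(sim.leaf_node_iter()):
                lf.taxon.label = labels[i]
            for e in sim.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(rng.uniform(0.1, 2.0))
            pdm = sim.phylogenetic_distance_matrix()
            mat = np.zeros((n, n))
            taxa = {t.label: t for t in sim.taxon_namespace}
            for i, li in enumerate(labels):
                for j, lj in enumerate(labels):
                    if i != j:
                        mat[i, j] = pdm.distance(taxa[li], taxa[lj])
            rec = nj_tree(DistanceMatrix(labels, mat))
            want = {frozenset(p) for p in nontrivial_splits(sim)}
            got = {frozenset(p) for p in nontrivial_splits(rec)}
            assert got == want

    def test_symmetry_required(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    def test_newick_roundtrip(self, tmp_path):
        D = DistanceMatrix(
            ["a_1", "b_1", "c_1"],
            np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float),
        )
        tree = nj_tree(D)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert {lf.taxon.label for lf in back.leaf_node_iter()} == {"a_1", "b_1", "c_1"}


class TestMatchingSplits:
    def test_self_distance_zero(self):
        t = _tree("((a,b),(c,d),(e,f));")
        assert matching_splits(t, t) == (0, 0.0)

    def test_four_leaf_conflict(self):
        t1 = _tree("((a,b),(c,d));")
        t2 = _tree("((a,c),(b,d));")
        ms, _ = matching_splits(t1, t2)
        assert ms == 2

    def test_four_leaf_equals_exhaustive_oracle(self):
        """Minimum-cost matching equals brute-force over all pairings."""
        from itertools import permutations

        t1 = _tree("(((a,b),c),(d,(e,f)));")
        t2 = _tree("(((a,c),b),(e,(d,f)));")
        s1 = nontrivial_splits(t1)
        s2 = nontrivial_splits(t2)
        assert len(s1) == len(s2)

        def cost(x, y):
            return min(len(x[0] ^ y[0]), len(x[0] ^ y[1]))

        oracle = min(
            sum(cost(a, b) for a, b in zip(s1, perm))
            for perm in permutations(s2)
        )
        assert matching_splits(t1, t2)[0] == oracle

    def test_star_normalization(self):
        t = _tree("((a,b),(c,d));")
        ms, pct = matching_splits(t, star_tree(list("abcd")))
        assert ms == 2
        assert pct == 100.0

    def test_published_percentage(self):
        """MS 582 against a star-tree MS of 722 is the printed 81% figure."""
        assert round(ms_percent_of_star(582, 722)) == 81

    def test_symmetry_and_triangle_with_star(self):
        t1 = _tree("(((a,b),c),((d,e),f));")
        t2 = _tree("(((a,f),c),((d,b),e));")
        ms12 = matching_splits(t1, t2)[0]
        assert ms12 == matching_splits(t2, t1)[0]
        star = star_tree(list("abcdef"))
        assert ms12 <= matching_splits(t1, star)[0] + matching_splits(star, t2)[0]

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            matching_splits(_tree("((a,b),(c,d));"), _tree("((a,b),(c,e));"))


class TestGsi:
    def test_monophyletic_group_is_one(self):
        t = _tree("(((a,b),(c,d)),((e,f),(g,h)));")
        assert gsi(t, {"a", "b"}) == 1.0
        assert gsi(t, {"a", "b", "c", "d"}) == 1.0

    def test_dispersed_pair_matches_direct_formula(self):
        """Two leaves on opposite sides of a balanced 8-leaf tree:
        gs = 1/5 over five uniting binary nodes, gs_min = 1/7,
        gsi = (1/5 - 1/7) / (1 - 1/7) = 1/15."""
        t = _tree("(((a,b),(c,d)),((e,f),(g,h)));")
        assert gsi(t, {"a", "e"}) == pytest.approx(1 / 15)

    def test_tighter_grouping_never_decreases(self):
        t = _tree("(((a,b),(c,d)),((e,f),(g,h)));")
        dispersed = gsi(t, {"a", "e", "g"})
        closer = gsi(t, {"e", "g", "h"})
        mono = gsi(t, {"e", "f", "g", "h"}) - 0.5  # strictly monophyletic
        assert dispersed < closer
        assert closer < mono + 1.0  # mono == 1.0
        assert gsi(t, {"e", "f", "g", "h"}) == 1.0

    def test_group_validation(self):
        t = _tree("((a,b),(c,d));")
        with pytest.raises(ValueError):
            gsi(t, {"a"})
        with pytest.raises(ValueError):
            gsi(t, {"a", "z"})
        with pytest.raises(ValueError):
            gsi(t, {"a", "b", "c", "d"})


class TestCladeRecovery:
    def test_structured_tree_all_monophyletic(self):
        t = _tree("(((A1_1,A1_2),(A2_1,A2_2)),((B1_1,B1_2),(B2_1,B2_2)));")
        labels = LabelTable.from_pairs(
            [(f"{s}_{m}", s[0], s) for s in ("A1", "A2", "B1", "B2") for m in (1, 2)]
        )
        rep = clade_recovery(t, labels)
        assert all(e["monophyletic"] for e in rep.values())
        assert all(e["gsi"] == 1.0 for e in rep.values())

    def test_grafted_member_flagged(self):
        t = _tree("(((A1_1,B1_1),A1_2),((B1_2,B1_3),A1_3));")
        labels = LabelTable.from_pairs(
            [(x, x[0], x[:2]) for x in ("A1_1", "A1_2", "A1_3", "B1_1", "B1_2", "B1_3")]
        )
        rep = clade_recovery(t, labels)
        assert rep["A1"]["monophyletic"] is False
        assert rep["A1"]["gsi"] < 1.0

    def test_singletons_not_applicable(self):
        t = _tree("((A1_1,A1_2),(B1_1,(C1_1,C1_2)));")
        labels = LabelTable.from_pairs(
            [("A1_1", "A", "A1"), ("A1_2", "A", "A1"),
             ("B1_1", "B", "B1"), ("C1_1", "C", "C1"), ("C1_2", "C", "C1")]
        )
        rep = clade_recovery(t, labels)
        assert rep["B"]["monophyletic"] is None
        assert rep["A"]["monophyletic"] is True

    def test_empty_labels_empty_report(self):
        t = _tree("((a,b),(c,d));")
        assert clade_recovery(t, LabelTable()) == {}


class TestBootstrapConsensus:
    def test_unanimous_topology_full_support(self):
        """Clearly separated groups: every replicate yields the same splits,
        the consensus keeps them all at 100%."""
        rng = np.random.default_rng(65)
        anc1, anc2 = random_dna(rng, 400), random_dna(rng, 400)
        seqs = []
        from phagemarker.synthdata import diverge

        for i in range(2):
            seqs.append(diverge(anc1, 0.02, seed=200 + i, new_id=f"x{i}"))
            seqs.append(diverge(anc2, 0.02, seed=300 + i, new_id=f"y{i}"))
        profiles = [ffp_profile(s, 8) for s in seqs]
        cons = bootstrap_consensus(profiles, replicates=30, mode="ffp", seed=1)
        splits = nontrivial_splits(cons)
        assert any(frozenset({"x0", "x1"}) in s for s in splits)

    def test_msa_mode_and_support_range(self):
        rows = ["ACGTACGTACGTACGTACAA", "ACGTACGTACGTACGTACAA",
                "TGCATGCATGCATGCAGGGG", "TGCATGCATGCATGCAGGGG"]
        ids = ["a1", "a2", "b1", "b2"]
        cons = bootstrap_consensus((ids, rows), replicates=25, mode="msa", seed=2)
        labels = [
            float(nd.label) for nd in cons.preorder_node_iter()
            if nd.label and not nd.is_leaf()
        ]
        assert labels
        assert all(50.0 < s <= 100.0 for s in labels)

    def test_replicates_validated(self):
        with pytest.raises(ValueError):
            bootstrap_consensus(([], []), replicates=0, mode="msa")


class TestFFPPipeline:
    def test_distance_matrix_labels(self, default_panel):
        genomes, _, _, _ = default_panel
        profiles = [ffp_profile(g, 20) for g in genomes[:5]]
        dm = ffp_distance_matrix(profiles)
        assert dm.labels == [g.id for g in genomes[:5]]
        assert dm.matrix.shape == (5, 5)
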