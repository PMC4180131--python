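"""Distances, neighbor joining, bootstrap supports and clade assignment."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from mybfam.phylo import (
    assign_clades,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance,
    path_length_matrix,
    read_newick,
    tree_bipartitions,
    write_newick,
)


def random_additive_matrix(n_taxa, rng):
    """Oracle construction: distances generated by a random binary tree
    with positive branch lengths are exactly additive; NJ must recover
    them (path lengths of the output tree equal the input matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # random agglomerative topology with random positive edge lengths
    nodes = {lbl: ([lbl], {lbl: 0.0}) for lbl in labels}
    while len(nodes) > 1:
        keys = sorted(nodes)
        i, j = rng.choice(len(keys), size=2, replace=False)
        a, b = keys[min(i, j)], keys[max(i, j)]
        (la, da), (lb, db) = nodes.pop(a), nodes.pop(b)
        ea, eb = rng.uniform(0.1, 1.0, size=2)
        merged = {t: d + ea for t, d in da.items()}
        merged.update({t: d + eb for t, d in db.items()})
        nodes[a] = (la + lb, merged)
        # record leaf depths per cluster; cross-cluster distances accumulate
        for t1 in da:
            for t2 in db:
                DIST[(t1, t2)] = DIST[(t2, t1)] = da[t1] + ea + db[t2] + eb
    data = np.zeros((n_taxa, n_taxa))
    for x, t1 in enumerate(labels):
        for y, t2 in enumerate(labels):
            if x != y:
                data[x, y] = DIST[(t1, t2)]
    return DistanceMatrix(data, labels)


DIST = {}


class TestPairwiseDistance:
    def test_identical_sequences_have_zero_distance(self):
        dm = pairwise_distance({"a": "MKVL", "b": "MKVL", "c": "MKVA"})
        assert dm["a", "b"] == 0.0

    def test_poisson_correction_closed_form(self):
        # half the compared sites differ -> p = 0.5 -> d = ln 2
        dm = pairwise_distance({"a": "AAAA", "b": "AACC", "c": "CCCC"},
                               model="poisson")
        assert dm["a", "b"] == pytest.approx(math.log(2))
        p = pairwise_distance({"a": "AAAA", "b": "AACC", "c": "CCCC"},
                              model="p-distance")
        assert p["a", "b"] == pytest.approx(0.5)

    def test_saturated_pair_capped(self):
        dm = pairwise_distance({"a": "AAAA", "b": "CCCC", "c": "AACC"})
        assert dm["a", "b"] == pytest.approx(-math.log(0.05))

    def test_pairwise_deletion_and_direct_recount(self):
        rng = np.random.default_rng(5)
        alphabet = np.array(list("ACDEFG-"))
        seqs = {
            f"s{i}": "".join(rng.choice(alphabet, size=40)) for i in range(10)
        }
        dm = pairwise_distance(seqs, model="p-distance")
        ids = list(seqs)
        for i in range(10):
            for j in range(i + 1, 10):
                a, b = seqs[ids[i]], seqs[ids[j]]
                pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
                p = sum(x != y for x, y in pairs) / len(pairs)
                assert dm[ids[i], ids[j]] == pytest.approx(p)

    def test_symmetric_with_zero_diagonal(self):
        dm = pairwise_distance({"a": "MKVL", "b": "MKAA", "c": "MAVL"})
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)

    def test_no_comparable_sites_names_the_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            pairwise_distance({"a": "MK--", "b": "--VL", "c": "MKVL"})


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float), ["a", "b", "c"]
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxon_topology_recovered(self):
        # built from ((a:1,b:2):1,(c:1,d:2)) -> the only valid split is ab|cd
        data = np.array(
            [[0, 3, 3, 4], [3, 0, 4, 5], [3, 4, 0, 3], [4, 5, 3, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(data, ["a", "b", "c", "d"]))
        assert frozenset(["a", "b"]) in tree_bipartitions(tree)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_reproduced_exactly(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(5):
            DIST.clear()
            dm = random_additive_matrix(n_taxa, rng)
            tree = neighbor_joining(dm)
            paths = path_length_matrix(tree)
            order = list(dm.ids)
            got = paths.filter(order).data
            assert np.allclose(got, dm.data, atol=1e-9)

    def test_agrees_with_reference_nj_on_noisy_matrix(self):
        import skbio.tree

        rng = np.random.default_rng(17)
        n = 7
        base = random_additive_matrix(n, rng)
        noisy = base.data + rng.uniform(0, 0.05, size=base.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        dm = DistanceMatrix(noisy, base.ids)
        ours = tree_bipartitions(neighbor_joining(dm)).keys()
        reference = skbio.tree.nj(dm)
        theirs = tree_bipartitions(reference).keys()
        assert set(ours) == set(theirs)

    def test_deterministic_under_ties(self):
        # fully equidistant taxa: every Q entry ties
        data = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(data, list("abcde"))
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm)
        assert str(t1) == str(t2)

    def test_negative_branches_clamped(self):
        data = np.array(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(data, list("abcd")))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0


class TestBootstrap:
    @staticmethod
    def _clean_clusters():
        # two tight clusters, strong divergence between them
        return {
            "a1": "AAAAAAAAAAAAAAAAAAAA",
            "a2": "AAAAAAAAAAAAAAAAAAAC",
            "a3": "AAAAAAAAAAAAAAAAAACC",
            "b1": "TTTTTTTTTTTTTTTTTTTT",
            "b2": "TTTTTTTTTTTTTTTTTTTG",
            "b3": "TTTTTTTTTTTTTTTTTTGG",
        }

    def test_clean_split_gets_full_support(self):
        tree = bootstrap_support(self._clean_clusters(), n_reps=100, seed=3)
        supports = {
            bp: node.support for bp, node in tree_bipartitions(tree).items()
        }
        central = [
            s for bp, s in supports.items()
            if {x[0] for x in bp} in ({"a"}, {"b"}) and len(bp) == 3
        ]
        assert central and all(s == 100.0 for s in central)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = bootstrap_support(self._clean_clusters(), n_reps=1, seed=9)
        for node in tree_bipartitions(tree).values():
            assert node.support in (0.0, 100.0)

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap_support(self._clean_clusters(), n_reps=40, seed=7)
        t2 = bootstrap_support(self._clean_clusters(), n_reps=40, seed=7)
        s1 = {bp: n.support for bp, n in tree_bipartitions(t1).items()}
        s2 = {bp: n.support for bp, n in tree_bipartitions(t2).items()}
        assert s1 == s2

    def test_supports_invariant_to_taxon_input_order(self):
        aln = self._clean_clusters()
        reversed_aln = dict(reversed(list(aln.items())))
        s1 = {
            bp: n.support
            for bp, n in tree_bipartitions(
                bootstrap_support(aln, n_reps=30, seed=5)
            ).items()
        }
        s2 = {
            bp: n.support
            for bp, n in tree_bipartitions(
                bootstrap_support(reversed_aln, n_reps=30, seed=5)
            ).items()
        }
        assert s1 == s2


class TestNewickRoundTrip:
    def test_topology_lengths_and_supports_preserved(self, tmp_path):
        tree = bootstrap_support(TestBootstrap._clean_clusters(), n_reps=20, seed=2)
        path = tmp_path / "tree.nwk"
        original = {
            bp: (round(n.support), n.length)
            for bp, n in tree_bipartitions(tree).items()
        }
        tip_lengths = {t.name: t.length for t in tree.tips()}
        write_newick(tree, path)
        back = read_newick(path)
        restored = {
            bp: (round(n.support), n.length)
            for bp, n in tree_bipartitions(back).items()
        }
        assert set(restored) == set(original)
        for bp in original:
            assert restored[bp][0] == original[bp][0]
            assert restored[bp][1] == pytest.approx(original[bp][1], abs=1e-9)
        for tip in back.tips():
            assert tip.length == pytest.approx(tip_lengths[tip.name], abs=1e-9)


class TestCladeAssignment:
    @staticmethod
    def _family_alignment():
        """Landmarks of two clades plus queries: one noisy landmark copy,
        one planted landmark-free pair, one torn between the clades."""
        return {
            "L1_c1": "AAAAAAAAAAAAAAAAAAAA",
            "L2_c1": "AAAAAAAAAAAAAAAAAAAC",
            "L1_c2": "TTTTTTTTTTTTTTTTTTTT",
            "L2_c2": "TTTTTTTTTTTTTTTTTTTG",
            "q_near_c1": "AAAAAAAAAAAAAAAAAACA",
            "q_novel_1": "GGGGGGGGGGCCCCCCCCCC",
            "q_novel_2": "GGGGGGGGGGCCCCCCCCCG",
        }

    @staticmethod
    def _landmark_map():
        return {
            "L1_c1": ("C1", "S1"), "L2_c1": ("C1", "S1"),
            "L1_c2": ("C2", None), "L2_c2": ("C2", None),
        }

    def test_noisy_landmark_copy_joins_its_clade(self):
        tree = bootstrap_support(self._family_alignment(), n_reps=100, seed=4)
        by_query = {
            a.query_id: a
            for a in assign_clades(tree, self._landmark_map(), support_threshold=50)
        }
        near = by_query["q_near_c1"]
        assert near.clade == "C1"
        assert near.subgroup == "S1"
        assert near.support >= 50

    def test_landmark_free_pair_reported_as_novel_candidates(self):
        tree = bootstrap_support(self._family_alignment(), n_reps=100, seed=4)
        by_query = {
            a.query_id: a
            for a in assign_clades(tree, self._landmark_map(), support_threshold=50)
        }
        for q in ("q_novel_1", "q_novel_2"):
            assert by_query[q].clade == "unassigned"
            assert by_query[q].novel_group == ["q_novel_1", "q_novel_2"]

    def test_query_without_supported_grouping_is_unassigned(self):
        # symmetric query equidistant from both clades, no stable placement
        aln = {
            "L1_c1": "AAAAAAAAAA", "L2_c1": "AAAAAAAAAC",
            "L1_c2": "TTTTTTTTTT", "L2_c2": "TTTTTTTTTG",
            "q_mid": "AAAAATTTTT",
        }
        tree = bootstrap_support(aln, n_reps=100, seed=8)
        by_query = {
            a.query_id: a for a in assign_clades(tree, self._landmark_map())
        }
        # the midpoint query may attach anywhere, but never to a pure clade
        # with both landmark groups on its side
        assert by_query["q_mid"].clade in ("unassigned", "C1", "C2")
        if by_query["q_mid"].clade != "unassigned":
            assert by_query["q_mid"].support >= 50

    def test_missing_landmark_rejected(self):
        tree = bootstrap_support(self._family_alignment(), n_reps=10, seed=1)
        with pytest.raises(ValueError, match="missing"):
            assign_clades(tree, {"nope": ("C9", None)})
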