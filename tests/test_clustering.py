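"""Pearson distance, UPGMA against the scipy oracle, Newick, concordance."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from codonclust.clustering import (
    Dendrogram,
    DistanceMatrix,
    concordance,
    cophenetic,
    cut_tree,
    distance_matrix,
    pearson_r,
    to_newick,
    upgma,
)
from codonclust.codon_metrics import RscuVector
from codonclust.genetics import CANONICAL_CODONS

N = len(CANONICAL_CODONS)


def vec(values, source_id="v", defined=None):
    """RSCU-shaped vector: given values in the first positions, rest masked."""
    full = np.zeros(N)
    mask = np.ones(N, dtype=bool)
    for i, val in enumerate(values):
        full[i] = val
        mask[i] = False
    if defined is not None:
        mask[:] = True
        for i in defined:
            mask[i] = False
    return RscuVector(full, mask, source_id=source_id)


class TestPearson:
    def test_self_correlation_is_one(self):
        u = vec([1.0, 2.0, 0.5, 1.5])
        assert pearson_r(u, u) == pytest.approx(1.0)

    def test_positive_affine_transform_is_one(self):
        u = vec([1.0, 2.0, 0.5, 1.5])
        v = vec([2 * x + 3 for x in [1.0, 2.0, 0.5, 1.5]], "w")
        assert pearson_r(u, v) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        u = vec([1, 2, 3, 4], "u")
        v = vec([2, 1, 4, 3], "v")
        assert pearson_r(u, v) == pytest.approx(0.6)

    def test_pairwise_complete_masking(self):
        """A position undefined in either vector is dropped from the pair."""
        u = vec([1, 2, 3, 4, 99], "u")
        v = vec([2, 1, 4, 3, 0], "v")
        v.undefined_mask[4] = True  # drop the discordant 5th position
        assert pearson_r(u, v) == pytest.approx(0.6)

    def test_too_few_shared_positions_raises(self):
        u = vec([1, 2], "u")
        v = vec([2, 1], "v")
        with pytest.raises(ValueError, match="shared"):
            pearson_r(u, v)

    def test_zero_variance_names_both_ids(self):
        u = vec([1.0, 1.0, 1.0, 1.0], "flat")
        v = vec([1, 2, 3, 4], "ok")
        with pytest.raises(ValueError, match="flat.*ok|ok.*flat"):
            pearson_r(u, v)


class TestDistanceMatrix:
    def test_identical_vectors_distance_zero(self):
        u = vec([1, 2, 3, 4], "a")
        w = vec([1, 2, 3, 4], "b")
        dm = distance_matrix([u, w])
        assert dm.d[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_distance_200(self):
        u = vec([1, 2, 3, 4], "a")
        w = vec([4, 3, 2, 1], "b")
        assert distance_matrix([u, w]).d[0, 1] == pytest.approx(200.0)

    def test_r06_pair_gives_40(self):
        u = vec([1, 2, 3, 4], "a")
        w = vec([2, 1, 4, 3], "b")
        assert distance_matrix([u, w]).d[0, 1] == pytest.approx(40.0)

    def test_reorder_invariance(self, rng):
        vs = [vec(rng.uniform(0, 2, 8), f"g{i}") for i in range(5)]
        dm = distance_matrix(vs)
        perm = [3, 1, 4, 0, 2]
        dm_p = distance_matrix([vs[i] for i in perm])
        assert np.allclose(dm_p.d, dm.d[np.ix_(perm, perm)])

    def test_errors_name_the_pair(self):
        u = vec([1.0, 1.0, 1.0], "flat")
        w = vec([1, 2, 3], "ok")
        with pytest.raises(ValueError, match="flat"):
            distance_matrix([u, w])


def three_leaf_matrix():
    d = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
    return DistanceMatrix(ids=["A", "B", "C"], d=d)


class TestUpgma:
    def test_three_leaf_merge_heights(self):
        tree = upgma(three_leaf_matrix())
        assert [h for _, _, h in tree.merges] == [1.0, 4.0]
        first_left, first_right, _ = tree.merges[0]
        assert {first_left, first_right} == {0, 1}  # A and B merge first

    def test_two_leaves(self):
        dm = DistanceMatrix(ids=["X", "Y"], d=np.array([[0.0, 6.0], [6.0, 0.0]]))
        tree = upgma(dm)
        assert tree.merges == [(0, 1, 3.0)]

    def test_tie_rule_deterministic_and_heights_unchanged(self):
        """Two equal minimal pairs: lexicographic merge order, same heights."""
        d = np.array(
            [
                [0.0, 2.0, 9.0, 9.0],
                [2.0, 0.0, 9.0, 9.0],
                [9.0, 9.0, 0.0, 2.0],
                [9.0, 9.0, 2.0, 0.0],
            ]
        )
        tree = upgma(DistanceMatrix(ids=["B", "D", "A", "C"], d=d))
        # pair (A,C) sorts before (B,D): leaves 2,3 merge first
        left, right, h = tree.merges[0]
        assert {left, right} == {2, 3} and h == 1.0
        assert [h for *_, h in tree.merges] == [1.0, 1.0, 4.5]

    def test_weighted_average_uses_cluster_sizes(self):
        # after merging A,B (d=2), d(AB,C) = (4 + 10)/2 = 7; then D joins
        d = np.array(
            [
                [0.0, 2.0, 4.0, 20.0],
                [2.0, 0.0, 10.0, 20.0],
                [4.0, 10.0, 0.0, 20.0],
                [20.0, 20.0, 20.0, 0.0],
            ]
        )
        tree = upgma(DistanceMatrix(ids=list("ABCD"), d=d))
        assert [round(h, 6) for *_, h in tree.merges] == [1.0, 3.5, 10.0]

    def test_matches_scipy_average_linkage_on_random_matrices(self, rng):
        """Cophenetic distances equal scipy's average-linkage oracle, n <= 8."""
        for _ in range(150):
            n = int(rng.integers(2, 9))
            condensed = rng.uniform(1.0, 100.0, size=n * (n - 1) // 2)
            dm = DistanceMatrix(
                ids=[f"L{i}" for i in range(n)], d=squareform(condensed)
            )
            ours = cophenetic(upgma(dm)).d
            ref = squareform(cophenet(linkage(condensed, method="average")))
            assert np.allclose(ours, ref, atol=1e-9)

    def test_ultrametric_three_point_condition(self, rng):
        n = 7
        condensed = rng.uniform(1.0, 50.0, size=n * (n - 1) // 2)
        coph = cophenetic(
            upgma(DistanceMatrix(ids=[f"L{i}" for i in range(n)],
                                 d=squareform(condensed)))
        ).d
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    assert max(coph[a, c], coph[b, c]) >= coph[a, b] - 1e-9


class TestNewickAndCophenetic:
    def test_three_leaf_newick_branch_lengths(self):
        tree = upgma(three_leaf_matrix())
        newick = to_newick(tree)
        # ((A:1,B:1):3,C:4); up to child order
        assert "A:1" in newick and "B:1" in newick and "C:4" in newick
        assert ":3" in newick and newick.endswith(";")

    def test_newick_roundtrip_preserves_heights(self):
        from io import StringIO

        from Bio import Phylo

        tree = upgma(three_leaf_matrix())
        parsed = Phylo.read(StringIO(to_newick(tree)), "newick")
        depths = parsed.depths()
        leaf_depths = {t.name: d for t, d in depths.items() if t.name}
        assert leaf_depths == pytest.approx({"A": 4.0, "B": 4.0, "C": 4.0})
        # cophenetic via the parsed tree matches the dendrogram's contract
        assert parsed.distance("A", "B") == pytest.approx(2.0)
        assert parsed.distance("A", "C") == pytest.approx(8.0)

    def test_cophenetic_matches_input_for_ultrametric_input(self):
        tree = upgma(three_leaf_matrix())
        coph = cophenetic(tree)
        assert coph.d == pytest.approx(three_leaf_matrix().d)


class TestCutAndConcordance:
    def test_clean_cut_recovers_labels(self):
        tree = upgma(three_leaf_matrix())
        labels = {"A": "x", "B": "x", "C": "y"}
        assert concordance(tree, labels, 2) == pytest.approx(1.0)

    def test_cut_tree_group_count(self):
        tree = upgma(three_leaf_matrix())
        assert len(set(cut_tree(tree, 2).values())) == 2
        assert len(set(cut_tree(tree, 3).values())) == 3

    def test_degenerate_single_label_all_singletons(self):
        """One label, k=n: no pairs co-clustered in the cut, index is 0."""
        tree = upgma(three_leaf_matrix())
        labels = {"A": "x", "B": "x", "C": "x"}
        assert concordance(tree, labels, 3) == pytest.approx(0.0)

    def test_unlabeled_leaf_raises(self):
        tree = upgma(three_leaf_matrix())
        with pytest.raises(ValueError, match="unlabeled"):
            concordance(tree, {"A": "x", "B": "x"}, 2)

    def test_random_labels_score_below_truth(self, rng, small_cohort):
        from codonclust.pipeline import genome_metrics

        records, truth = small_cohort
        vectors = [genome_metrics(r)[1] for r in records]
        tree = upgma(distance_matrix(vectors))
        true_score = concordance(tree, truth, 3)
        ids = list(truth)
        for _ in range(5):
            shuffled = dict(zip(ids, rng.permutation([truth[i] for i in ids])))
            if all(shuffled[i] == truth[i] for i in ids):
                continue
            assert concordance(tree, shuffled, 3) < true_score
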