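"""Alignment curation, distance corrections, BioNJ and bootstrap."""

import numpy as np
import pytest
from skbio import TreeNode

from rasevol.io import AlignedSet, RasevolError
from rasevol.phylo import (DistanceMatrix, bionj, bipartitions,
                           bootstrap_support, curate_alignment,
                           protein_distance, read_newick, robinson_foulds,
                           write_newick)
from rasevol.simulate import archetype, balanced_tree, evolve_family


def random_binary_tree(n, rng):
    """Random unrooted binary tree with branch lengths in [0.05, 0.5]."""
    root = TreeNode()
    for i in range(3):
        leaf = TreeNode(name=f"t{i}")
        leaf.length = float(rng.uniform(0.05, 0.5))
        root.append(leaf)
    for i in range(3, n):
        edges = [node for node in root.traverse() if node is not root]
        target = edges[int(rng.integers(0, len(edges)))]
        mid = TreeNode()
        parent = target.parent
        parent.remove(target)
        parent.append(mid)
        mid.length = target.length / 2
        target.length = target.length / 2
        mid.append(target)
        leaf = TreeNode(name=f"t{i}")
        leaf.length = float(rng.uniform(0.05, 0.5))
        mid.append(leaf)
    return root


def path_distance_matrix(tree):
    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = [t.name for t in tips]
    n = len(tips)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tips[i].distance(tips[j])
    return DistanceMatrix(labels, values)


class TestCurate:
    def test_gap_free_unchanged(self):
        aln = AlignedSet(["a", "b"], ["MKVLY", "MKALY"])
        assert curate_alignment(aln).rows == aln.rows

    def test_gappy_column_dropped(self):
        aln = AlignedSet(["a", "b"], ["MK-LY", "MKVLY"])
        curated = curate_alignment(aln, max_gap_fraction=0.2)
        assert curated.rows == ["MKLY", "MKLY"]

    def test_threshold_one_keeps_everything(self):
        aln = AlignedSet(["a", "b"], ["MK-LY", "MKVLY"])
        assert curate_alignment(aln, max_gap_fraction=1.0).rows == aln.rows

    def test_everything_dropped_errors(self):
        aln = AlignedSet(["a", "b"], ["M-", "-K"])
        with pytest.raises(RasevolError):
            curate_alignment(aln, max_gap_fraction=0.0)


class TestProteinDistance:
    def test_identical_rows_zero(self):
        aln = AlignedSet(["a", "b"], ["MKVLY", "MKVLY"])
        for model in ("p", "poisson", "kimura"):
            assert protein_distance(aln, model).values[0, 1] == 0.0

    def test_poisson_closed_form(self):
        aln = AlignedSet(["a", "b"], ["AAAA", "AACC"])  # p = 0.5
        d = protein_distance(aln, "poisson").values[0, 1]
        assert d == pytest.approx(-np.log(0.5), abs=1e-4)
        assert d == pytest.approx(0.6931, abs=1e-4)

    def test_kimura_closed_form(self):
        aln = AlignedSet(["a", "b"], ["A" * 7 + "CCC", "A" * 7 + "DDD"])  # p=0.3
        d = protein_distance(aln, "kimura").values[0, 1]
        assert d == pytest.approx(-np.log(1 - 0.3 - 0.2 * 0.09), abs=1e-4)
        assert d == pytest.approx(0.3827, abs=1e-4)

    def test_corrections_ordered_kimura_ge_poisson_ge_p(self):
        for k in range(1, 7):  # p from 0.1 to 0.6
            row_b = "A" * (10 - k) + "C" * k
            aln = AlignedSet(["a", "b"], ["A" * 10, row_b])
            p = protein_distance(aln, "p").values[0, 1]
            poisson = protein_distance(aln, "poisson").values[0, 1]
            kimura = protein_distance(aln, "kimura").values[0, 1]
            assert kimura >= poisson >= p

    def test_gapped_columns_excluded_pairwise(self):
        aln = AlignedSet(["a", "b", "c"], ["MK-LY", "MKVLY", "MKVAY"])
        dm = protein_distance(aln, "p")
        assert dm.site_counts[0, 1] == 4  # a/b share 4 gap-free columns
        assert dm.site_counts[1, 2] == 5

    def test_saturated_pair_hits_ceiling(self):
        aln = AlignedSet(["a", "b"], ["AAAA", "CCCC"])  # p = 1
        with pytest.warns(UserWarning, match="saturated"):
            dm = protein_distance(aln, "poisson")
        assert dm.saturated[0, 1]
        assert np.isfinite(dm.values[0, 1])

    def test_no_comparable_columns_errors(self):
        aln = AlignedSet(["a", "b"], ["M-", "-K"])
        with pytest.raises(RasevolError, match="comparable"):
            protein_distance(aln, "p")


class TestBioNJ:
    def test_three_taxa_closed_form(self):
        values = np.array([[0.0, 0.3, 0.5],
                           [0.3, 0.0, 0.6],
                           [0.5, 0.6, 0.0]])
        tree = bionj(DistanceMatrix(["A", "B", "C"], values))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_two_taxa_single_split_edge(self):
        tree = bionj(DistanceMatrix(["A", "B"], np.array([[0.0, 0.4],
                                                          [0.4, 0.0]])))
        lengths = sorted(t.length for t in tree.tips())
        assert lengths == pytest.approx([0.2, 0.2])

    def test_additive_matrices_recovered_exactly(self):
        # oracle: path-length matrix of a random tree; BioNJ must return
        # RF distance 0 and reproduce every pairwise path length
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            truth = random_binary_tree(n, rng)
            dm = path_distance_matrix(truth)
            recovered = bionj(dm)
            assert robinson_foulds(truth, recovered) == 0
            tips = {t.name: t for t in recovered.tips()}
            for i, a in enumerate(dm.labels):
                for j in range(i + 1, len(dm.labels)):
                    b = dm.labels[j]
                    assert tips[a].distance(tips[b]) == pytest.approx(
                        dm.values[i, j], abs=1e-9)

    def test_non_symmetric_rejected(self):
        with pytest.raises(RasevolError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_internal_nodes_have_degree_three(self):
        rng = np.random.default_rng(7)
        tree = bionj(path_distance_matrix(random_binary_tree(8, rng)))
        for node in tree.non_tips(include_self=True):
            degree = len(node.children) + (0 if node.parent is None else 1)
            assert degree >= 3


class TestBootstrap:
    def test_true_split_strongly_supported(self):
        # two clades separated by a long internal branch; at 200 replicates
        # the true split must reach ≥95% support
        newick = ("((a1:0.05,a2:0.05):0.5,(b1:0.05,b2:0.05):0.5,"
                  "(c1:0.05,c2:0.05):0.5);")
        records, _ = evolve_family(archetype("KRAS4B-like"), newick,
                                   subs_per_site_per_branch=1.0,
                                   mask_respect=True, seed=11)
        aln = AlignedSet([r.id for r in records],
                         [r.residues for r in records])
        tree = bootstrap_support(aln, model="kimura", replicates=200, seed=3)
        supports = {}
        for node in tree.non_tips(include_self=False):
            side = frozenset(leaf.name for leaf in node.tips())
            supports[side] = float(node.name)
        for clade in ({"a1", "a2"}, {"b1", "b2"}, {"c1", "c2"}):
            matching = [s for side, s in supports.items()
                        if side == clade or side == set(aln.row_ids) - clade]
            assert matching and max(matching) >= 95.0

    def test_same_seed_identical_output(self, kras4b_family):
        records, _ = kras4b_family
        aln = AlignedSet([r.id for r in records[:6]],
                         [r.residues for r in records[:6]])
        t1 = bootstrap_support(aln, replicates=25, seed=5)
        t2 = bootstrap_support(aln, replicates=25, seed=5)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_within_0_100(self, kras4b_family):
        records, _ = kras4b_family
        aln = AlignedSet([r.id for r in records[:6]],
                         [r.residues for r in records[:6]])
        tree = bootstrap_support(aln, replicates=25, seed=5)
        for node in tree.non_tips(include_self=False):
            assert 0.0 <= float(node.name) <= 100.0

    def test_zero_replicates_rejected(self, kras4b_family):
        records, _ = kras4b_family
        aln = AlignedSet([r.id for r in records[:4]],
                         [r.residues for r in records[:4]])
        with pytest.raises(RasevolError):
            bootstrap_support(aln, replicates=0, seed=1)


class TestNewick:
    def test_three_leaf_shape(self):
        values = np.array([[0.0, 2.0, 2.0],
                           [2.0, 0.0, 2.0],
                           [2.0, 2.0, 0.0]])
        text = write_newick(bionj(DistanceMatrix(["A", "B", "C"], values)))
        assert text == "(A:1,B:1,C:1);"

    def test_round_trip_preserves_bipartitions_lengths_supports(self):
        rng = np.random.default_rng(9)
        tree = bionj(path_distance_matrix(random_binary_tree(7, rng)))
        for i, node in enumerate(tree.non_tips(include_self=False)):
            node.name = str(50 + i)
        text = write_newick(tree)
        back = read_newick(text)
        assert bipartitions(back) == bipartitions(tree)
        assert write_newick(back) == text

    def test_labels_with_metacharacters_quoted(self):
        tree = TreeNode.read(["(A,B);"])
        next(tree.tips()).name = "sp one"
        text = write_newick(tree)
        assert "'sp one'" in text
        back = read_newick(text)
        assert {t.name for t in back.tips()} == {"sp one", "B"}
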