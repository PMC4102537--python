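import math

import numpy as np
import pytest

from srvpan.genome_io import Gene, Genome
from srvpan.orthology import OrthologGroup
from srvpan.phylo import (
    AlignedGroup,
    DistanceMatrix,
    TreeNode,
    align_group,
    concat_and_distance,
    filter_columns,
    nj_tree,
    robinson_foulds,
)

from .oracles import gotoh_global_score, tree_path_distances


def panel_from(seqs: dict[str, str]) -> tuple[list[Genome], OrthologGroup]:
    panel = [
        Genome(gid, [Gene(f"{gid}_1", gid, seq)]) for gid, seq in seqs.items()
    ]
    group = OrthologGroup(
        "OG00001", {gid: f"{gid}_1" for gid in seqs}, seeded_by=sorted(seqs)[0]
    )
    return panel, group


class TestAlignGroup:
    def test_identical_sequences_align_gap_free(self):
        panel, group = panel_from({"A": "MKTAYIAK", "B": "MKTAYIAK", "C": "MKTAYIAK"})
        aligned = align_group(group, panel, reference="A")
        assert set(aligned.rows.values()) == {"MKTAYIAK"}
        assert aligned.kept_columns == list(range(8))

    def test_deletion_introduces_one_gap_column(self):
        panel, group = panel_from({"A": "MKTA", "B": "MKA"})
        aligned = align_group(group, panel, reference="A")
        assert aligned.length == 4
        gappy = [i for i in range(4) if "-" in {r[i] for r in aligned.rows.values()}]
        assert len(gappy) == 1
        # the projected row realizes the oracle's optimal global score
        from Bio.Align import PairwiseAligner, substitution_matrices

        aligner = PairwiseAligner(
            mode="global",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-12, extend_gap_score=-1,
        )
        assert int(aligner.score("MKTA", "MKA")) == gotoh_global_score("MKTA", "MKA")

    def test_alignment_at_least_as_long_as_longest_member(self):
        panel, group = panel_from({"A": "MKTA", "B": "MKTAYIAKLL", "C": "MKT"})
        aligned = align_group(group, panel, reference="A")
        assert aligned.length >= 10

    def test_singleton_group_rejected(self):
        panel, _ = panel_from({"A": "MKTA"})
        group = OrthologGroup("OG1", {"A": "A_1"}, seeded_by="A")
        with pytest.raises(ValueError):
            align_group(group, panel)


class TestFilterColumns:
    def test_gap_free_identical_block_keeps_everything(self):
        ag = AlignedGroup("g", {"A": "MKTA", "B": "MKTA"})
        assert filter_columns(ag).kept_columns == [0, 1, 2, 3]

    def test_column_with_gap_dropped(self):
        ag = AlignedGroup("g", {"A": "MKTA", "B": "MK-A"})
        assert filter_columns(ag).kept_columns == [0, 1, 3]

    def test_four_row_block_matches_hand_enumeration(self):
        # col0: all equal (keep); col1: 2/4 identical (keep, ties at 50%);
        # col2: gap (drop); col3: 4 distinct (drop, 25% < 50%)
        ag = AlignedGroup("g", {
            "A": "MKCA", "B": "MKDA", "C": "MLE-", "D": "MLFA",
        })
        assert filter_columns(ag).kept_columns == [0, 1]


class TestDistances:
    def test_p_distance(self):
        ag = AlignedGroup("g", {"A": "AAAA", "B": "AAAT"})
        ag.kept_columns = [0, 1, 2, 3]
        D = concat_and_distance([ag], correction="p")
        assert D.d[0, 1] == pytest.approx(0.25)

    def test_poisson_correction(self):
        ag = AlignedGroup("g", {"A": "AAAA", "B": "AAAT"})
        ag.kept_columns = [0, 1, 2, 3]
        D = concat_and_distance([ag], correction="poisson")
        assert D.d[0, 1] == pytest.approx(-math.log(0.75))

    def test_identical_strains_zero_matrix(self):
        ag = AlignedGroup("g", {"A": "MKTA", "B": "MKTA", "C": "MKTA"})
        ag.kept_columns = [0, 1, 2, 3]
        D = concat_and_distance([ag])
        assert np.all(D.d == 0)

    def test_saturated_poisson_rejected(self):
        ag = AlignedGroup("g", {"A": "AAAA", "B": "TTTT"})
        ag.kept_columns = [0, 1, 2, 3]
        with pytest.raises(ValueError):
            concat_and_distance([ag], correction="poisson")

    def test_groups_concatenated_in_group_id_order(self):
        a = AlignedGroup("OG2", {"A": "AA", "B": "AT"})
        a.kept_columns = [0, 1]
        b = AlignedGroup("OG1", {"A": "CC", "B": "CC"})
        b.kept_columns = [0, 1]
        D = concat_and_distance([a, b], correction="p")
        assert D.d[0, 1] == pytest.approx(0.25)  # 1 mismatch over 4 columns


def additive_matrix_from_tree(root: TreeNode) -> DistanceMatrix:
    dists = tree_path_distances(root)
    taxa = sorted(root.leaves())
    d = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            d[i, j] = d[j, i] = dists[tuple(sorted((a, taxa[j])))]
    return DistanceMatrix(taxa=taxa, d=d)


class TestNeighborJoining:
    # the additive 4-taxon example: (A:1, B:2) --1-- (C:3, D:4)
    FOUR = DistanceMatrix(
        taxa=["A", "B", "C", "D"],
        d=np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float),
    )

    def test_recovers_additive_four_taxon_tree(self):
        tree = nj_tree(self.FOUR)
        assert tree.root.bipartitions() == {frozenset({"A", "B"})}
        recovered = tree_path_distances(tree.root)
        for (a, b), expected in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert recovered[(a, b)] == pytest.approx(expected)

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(taxa=["A", "B", "C"], d=np.array(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float))
        tree = nj_tree(D)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_taxon_order_invariance(self):
        perm = [2, 0, 3, 1]
        D2 = DistanceMatrix(
            taxa=[self.FOUR.taxa[i] for i in perm],
            d=self.FOUR.d[np.ix_(perm, perm)],
        )
        t1, t2 = nj_tree(self.FOUR), nj_tree(D2)
        assert robinson_foulds(t1.root, t2.root) == 0

    def test_fewer_than_three_taxa_rejected(self):
        D = DistanceMatrix(taxa=["A", "B"], d=np.array([[0, 1], [1, 0]], dtype=float))
        with pytest.raises(ValueError):
            nj_tree(D)

    def test_exact_on_random_additive_matrices(self):
        """NJ must reproduce any tree metric exactly (four-point condition)."""
        from srvpan.synthetic_data import _random_tree

        rng = np.random.default_rng(5)
        for n_taxa in (4, 5, 7, 10):
            for _ in range(5):
                tree = _random_tree([f"T{i}" for i in range(n_taxa)], rng)
                D = additive_matrix_from_tree(tree)
                recovered = nj_tree(D)
                assert robinson_foulds(recovered.root, tree) == 0
                rec = tree_path_distances(recovered.root)
                truth = tree_path_distances(tree)
                for key, val in truth.items():
                    assert rec[key] == pytest.approx(val, abs=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        import skbio

        from srvpan.synthetic_data import _random_tree

        rng = np.random.default_rng(9)
        tree = _random_tree([f"T{i}" for i in range(6)], rng)
        D = additive_matrix_from_tree(tree)
        mine = nj_tree(D)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D.d, ids=D.taxa))
        ref_splits = set()
        all_taxa = frozenset(D.taxa)
        for node in ref.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(all_taxa) - 1:
                ref_splits.add(min(below, all_taxa - below,
                                   key=lambda s: (len(s), sorted(s))))
        assert ref_splits == mine.root.bipartitions()


class TestEndToEndTopology:
    def test_generating_topology_recovered_on_default_panel(self, run):
        assert robinson_foulds(run.tree.root, run.truth.tree) == 0

    def test_rf_distance_agrees_with_dendropy(self, run):
        import dendropy

        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=run.tree.newick, schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=run.truth.tree.newick() + "\n",
                               schema="newick", taxon_namespace=tns)
        t1.is_rooted = t2.is_rooted = False
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == robinson_foulds(run.tree.root, run.truth.tree)
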