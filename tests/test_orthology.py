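import pytest

from srvpan.genome_io import Gene, Genome
from srvpan.orthology import best_hit, build_groups, rbbh_pairs, srv
from srvpan.similarity import HitTable, RawHit, all_vs_all

from .oracles import enumerate_rbbh


def make_table(genes: dict[str, str], scores: dict[tuple[str, str], float]) -> HitTable:
    """Hand-built hit table: genes maps locus -> genome, scores raw values."""
    table = HitTable()
    for locus, genome in genes.items():
        table.register_gene(locus, genome)
    for (q, s), raw in scores.items():
        table.add(RawHit(q, s, raw, bit_score=float(raw), evalue=1.0 / (raw + 1)))
    return table


class TestSRV:
    def test_self_hit_is_100(self):
        hit = RawHit("a", "a", 16, 16.0, 0.0)
        assert srv(hit, 16) == 100.0

    def test_half_self_score(self):
        assert srv(RawHit("a", "b", 8, 8.0, 0.0), 16) == 50.0

    def test_above_threshold_arithmetic(self):
        assert srv(RawHit("a", "b", 6, 6.0, 0.0), 16) == 37.5

    def test_clamped_to_100(self):
        assert srv(RawHit("a", "b", 20, 20.0, 0.0), 16) == 100.0

    def test_missing_self_hit_names_locus(self):
        table = make_table({"a": "G1"}, {})
        with pytest.raises(KeyError, match="a"):
            table.self_score("a")

    def test_nonpositive_self_score_rejected(self):
        with pytest.raises(ValueError):
            srv(RawHit("a", "b", 8, 8.0, 0.0), 0)


class TestBestHit:
    def test_no_hits_gives_none(self):
        table = make_table({"a": "G1", "b": "G2"}, {("a", "a"): 100})
        assert best_hit("a", "G2", table) is None

    def test_max_score_wins(self):
        table = make_table(
            {"a": "G1", "x": "G2", "y": "G2"},
            {("a", "a"): 100, ("a", "x"): 40, ("a", "y"): 90},
        )
        assert best_hit("a", "G2", table).subject == "y"

    def test_tie_broken_by_smaller_tag(self):
        table = HitTable()
        for locus, genome in {"a": "G1", "x": "G2", "w": "G2"}.items():
            table.register_gene(locus, genome)
        table.add(RawHit("a", "a", 100, 100.0, 0.0))
        table.add(RawHit("a", "x", 90, 90.0, 1e-30))
        table.add(RawHit("a", "w", 90, 90.0, 1e-30))
        assert best_hit("a", "G2", table).subject == "w"


def two_genomes(tags_a, tags_b):
    gA = Genome("G1", [Gene(t, "G1", "M" * 10) for t in tags_a])
    gB = Genome("G2", [Gene(t, "G2", "M" * 10) for t in tags_b])
    return gA, gB


class TestRBBH:
    def test_identical_genomes_pair_every_gene(self, toy3_panel):
        g1 = toy3_panel[0]
        twin = Genome("T", [Gene(g.locus_tag + "t", "T", g.protein_seq) for g in g1.genes])
        table = all_vs_all([g1, twin])
        pairs = rbbh_pairs(g1, twin, table)
        assert pairs == [(g.locus_tag, g.locus_tag + "t") for g in g1.genes]
        for a, b in pairs:
            assert srv(table.get(a, b), table.self_score(a)) == 100.0

    def test_srv_exactly_35_is_excluded(self):
        gA, gB = two_genomes(["a"], ["b"])
        table = make_table(
            {"a": "G1", "b": "G2"},
            {("a", "a"): 100, ("b", "b"): 100, ("a", "b"): 35, ("b", "a"): 36},
        )
        assert rbbh_pairs(gA, gB, table) == []
        # strictly above in both directions qualifies
        table2 = make_table(
            {"a": "G1", "b": "G2"},
            {("a", "a"): 100, ("b", "b"): 100, ("a", "b"): 36, ("b", "a"): 36},
        )
        assert rbbh_pairs(gA, gB, table2) == [("a", "b")]

    def test_matches_enumeration_oracle_on_toy_scores(self):
        gA, gB = two_genomes(["a1", "a2", "a3"], ["b1", "b2", "b3"])
        genes = {t: "G1" for t in ("a1", "a2", "a3")} | {t: "G2" for t in ("b1", "b2", "b3")}
        self_scores = {t: 100 for t in genes}
        cross = {
            ("a1", "b1"): 90, ("b1", "a1"): 90,
            ("a1", "b2"): 50, ("b2", "a1"): 50,
            ("a2", "b2"): 60, ("b2", "a2"): 60,
            ("a3", "b3"): 30, ("b3", "a3"): 30,   # below SRV threshold
            ("a3", "b1"): 20, ("b1", "a3"): 20,
        }
        scores = {**{(t, t): 100 for t in genes}, **cross}
        table = make_table(genes, scores)
        expected = enumerate_rbbh(
            {"G1": ["a1", "a2", "a3"], "G2": ["b1", "b2", "b3"]}, scores, self_scores
        )
        assert set(rbbh_pairs(gA, gB, table)) == expected
        assert expected == {("a1", "b1"), ("a2", "b2")}


class TestBuildGroups:
    def test_single_genome_gives_singletons(self, toy3_panel):
        g1 = toy3_panel[0]
        table = all_vs_all([g1])
        groups = build_groups([g1], table, "G1")
        assert len(groups) == g1.n_orfs
        assert all(g.size == 1 for g in groups)

    def test_two_identical_genomes_pair_everything(self, toy3_panel):
        g1 = toy3_panel[0]
        twin = Genome("T", [Gene(g.locus_tag + "t", "T", g.protein_seq) for g in g1.genes])
        for reference in ("G1", "T"):
            groups = build_groups([g1, twin], all_vs_all([g1, twin]), reference)
            assert sorted(g.size for g in groups) == [2] * g1.n_orfs

    def test_toy3_partition_matches_enumeration(self, toy3_panel):
        table = all_vs_all(toy3_panel)
        groups = build_groups(toy3_panel, table, "G1")
        members = {frozenset(g.members.values()) for g in groups}
        assert members == {
            frozenset({"a1", "a2", "a3"}),
            frozenset({"b1", "b2"}),
            frozenset({"c1"}), frozenset({"d2"}), frozenset({"e3"}),
        }

    def test_unknown_reference_rejected(self, toy3_panel):
        with pytest.raises(ValueError, match="nope"):
            build_groups(toy3_panel, all_vs_all(toy3_panel), "nope")

    def test_partition_property(self, run):
        """Every gene lands in exactly one group."""
        seen = {}
        for group in run.groups:
            for locus in group.members.values():
                assert locus not in seen
                seen[locus] = group.group_id
        total = sum(g.n_orfs for g in run.panel)
        assert len(seen) == total

    def test_gene_order_does_not_change_groups(self, toy3_panel):
        reordered = [
            Genome(g.genome_id, list(reversed(g.genes))) for g in toy3_panel
        ]
        a = build_groups(toy3_panel, all_vs_all(toy3_panel), "G1")
        b = build_groups(reordered, all_vs_all(reordered), "G1")
        assert {frozenset(g.members.values()) for g in a} == {
            frozenset(g.members.values()) for g in b
        }

    def test_lower_threshold_never_shrinks_reference_groups(self, toy3_panel):
        table = all_vs_all(toy3_panel)
        strict = build_groups(toy3_panel, table, "G1", srv_threshold=60.0)
        loose = build_groups(toy3_panel, table, "G1", srv_threshold=35.0)
        strict_ref = {g.members["G1"]: g.size for g in strict if "G1" in g.members and g.seeded_by == "G1"}
        loose_ref = {g.members["G1"]: g.size for g in loose if "G1" in g.members and g.seeded_by == "G1"}
        for locus, size in strict_ref.items():
            assert loose_ref[locus] >= size
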