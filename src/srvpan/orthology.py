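"""Score-ratio (SRV) normalization, reciprocal-best-hit pairs, ortholog groups.

A hit's SRV is its score expressed as a percentage of the query's self-hit
score (the maximum attainable), so SRV ranges over [0, 100] with the self-hit
at 100. Two cross-genome genes are orthologs when they are each other's best
hit and the SRV strictly exceeds the threshold (default 35) in both
directions.

Multi-genome groups are assembled reference-seeded: pass 1 founds one group
per reference gene and attaches, per non-reference genome, the gene paired
with it by RBBH; pass 2 sweeps the remaining genes genome by genome in panel
order, seeding new groups among still-unassigned genes. No transitive closure
is applied through non-reference genomes for reference-seeded groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Genome
from .similarity import HitTable, RawHit

DEFAULT_SRV_THRESHOLD = 35.0


def srv(hit: RawHit, self_score_of_query: float) -> float:
    """100 * score / self-score of the query, clamped to [0, 100]."""
    if self_score_of_query is None or self_score_of_query <= 0:
        raise ValueError(f"non-positive self-hit score for query {hit.query!r}")
    value = 100.0 * hit.score / self_score_of_query
    return min(100.0, max(0.0, value))


@dataclass
class SRVHit:
    query: str
    subject: str
    raw_score: float
    srv: float


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, str] = field(default_factory=dict)  # genome_id -> locus_tag
    seeded_by: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


def best_hit(query: str, target_genome_id: str, table: HitTable) -> SRVHit | None:
    """Best hit of ``query`` into a target genome, or None.

    Ranking: maximal score, then lower E-value, then lexicographically
    smallest subject locus tag.
    """
    hits = table.hits_into(query, target_genome_id)
    if not hits:
        return None
    top = min(hits, key=lambda h: (-h.score, h.evalue, h.subject))
    return SRVHit(
        query=query,
        subject=top.subject,
        raw_score=top.score,
        srv=srv(top, table.self_score(query)),
    )


def rbbh_pairs(
    gA: Genome,
    gB: Genome,
    table: HitTable,
    srv_threshold: float = DEFAULT_SRV_THRESHOLD,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs between two genomes.

    A pair (a, b) qualifies iff b is a's best hit in B, a is b's best hit in
    A, and SRV > threshold strictly in both directions. Each gene appears in
    at most one pair.
    """
    if gA.genome_id == gB.genome_id:
        raise ValueError("rbbh_pairs requires two distinct genomes")
    pairs = []
    for gene in gA.genes:
        fwd = best_hit(gene.locus_tag, gB.genome_id, table)
        if fwd is None or fwd.srv <= srv_threshold:
            continue
        rev = best_hit(fwd.subject, gA.genome_id, table)
        if rev is None or rev.subject != gene.locus_tag or rev.srv <= srv_threshold:
            continue
        pairs.append((gene.locus_tag, fwd.subject))
    return sorted(pairs)


def build_groups(
    panel: list[Genome],
    table: HitTable,
    reference: str,
    srv_threshold: float = DEFAULT_SRV_THRESHOLD,
) -> list[OrthologGroup]:
    """Partition all panel genes into ortholog groups (reference-seeded)."""
    by_id = {g.genome_id: g for g in panel}
    if reference not in by_id:
        raise ValueError(f"reference genome {reference!r} not in panel")

    # pairwise RBBH maps keyed by (genome_a, genome_b), locus_a -> locus_b
    pair_map: dict[tuple[str, str], dict[str, str]] = {}

    def partner(locus: str, genome_a: str, genome_b: str) -> str | None:
        key = (genome_a, genome_b)
        if key not in pair_map:
            pairs = rbbh_pairs(by_id[genome_a], by_id[genome_b], table, srv_threshold)
            pair_map[key] = dict(pairs)
            pair_map[(genome_b, genome_a)] = {b: a for a, b in pairs}
        return pair_map[key].get(locus)

    assigned: set[str] = set()
    groups: list[OrthologGroup] = []
    counter = 0

    def new_group(seed_genome: str, seed_locus: str) -> OrthologGroup:
        nonlocal counter
        counter += 1
        group = OrthologGroup(
            group_id=f"OG{counter:05d}",
            members={seed_genome: seed_locus},
            seeded_by=seed_genome,
        )
        assigned.add(seed_locus)
        groups.append(group)
        return group

    panel_order = [g.genome_id for g in panel]
    others = [gid for gid in panel_order if gid != reference]

    # pass 1: one group per reference gene, filled by RBBH to the reference
    for gene in by_id[reference].genes:
        group = new_group(reference, gene.locus_tag)
        for gid in others:
            mate = partner(gene.locus_tag, reference, gid)
            if mate is not None and mate not in assigned:
                group.members[gid] = mate
                assigned.add(mate)

    # pass 2: remaining genes, genome by genome in panel order
    for gid in others:
        for gene in by_id[gid].genes:
            if gene.locus_tag in assigned:
                continue
            group = new_group(gid, gene.locus_tag)
            for gid2 in panel_order:
                if gid2 == gid or gid2 in group.members:
                    continue
                mate = partner(gene.locus_tag, gid, gid2)
                if mate is not None and mate not in assigned:
                    group.members[gid2] = mate
                    assigned.add(mate)

    return groups


def group_table_rows(groups: list[OrthologGroup], table: HitTable | None = None) -> list[dict]:
    """Flat rows for the group TSV: group_id, genome_id, locus_tag, seeded_by, srv_to_seed."""
    rows = []
    for group in groups:
        seed_locus = group.members[group.seeded_by]
        for genome_id in sorted(group.members):
            locus = group.members[genome_id]
            srv_to_seed = ""
            if table is not None and locus != seed_locus:
                hit = table.get(seed_locus, locus)
                if hit is not None:
                    srv_to_seed = f"{srv(hit, table.self_score(seed_locus)):.1f}"
            elif locus == seed_locus:
                srv_to_seed = "100.0"
            rows.append({
                "group_id": group.group_id,
                "genome_id": genome_id,
                "locus_tag": locus,
                "seeded_by": group.seeded_by,
                "srv_to_seed": srv_to_seed,
            })
    rows.sort(key=lambda r: (r["group_id"], r["genome_id"]))
    return rows
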