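"""Presence/absence screen for seed surface-protein loci, identity and G+C.

For each seed query protein the best hit in each genome must qualify as an
RBBH-style match: the seed's best gene in the genome, reciprocally the gene's
best seed, with SRV strictly above the threshold in both directions. Operons
(named groups of seeds) are called present only when every member seed is
present; partial matches are reported as "partial".

G+C content is computed over A/C/G/T with N excluded from numerator and
denominator, rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .genome_io import Gene, Genome
from .orthology import DEFAULT_SRV_THRESHOLD
from .similarity import ScoringParams, _aligner, _kmer_set, bits_and_evalue


@dataclass
class PresenceMatrix:
    seeds: list[str]
    genomes: list[str]
    cells: dict[str, dict[str, str | None]]           # seed -> genome -> locus or None
    srv_values: dict[str, dict[str, float]] = field(default_factory=dict)
    operon_calls: dict[str, dict[str, str]] = field(default_factory=dict)

    def present(self, seed: str, genome: str) -> bool:
        return self.cells[seed][genome] is not None


def screen(
    seeds: list[tuple[str, str]],
    panel: list[Genome],
    srv_threshold: float = DEFAULT_SRV_THRESHOLD,
    operons: dict[str, list[str]] | None = None,
    params: ScoringParams | None = None,
) -> PresenceMatrix:
    """Match seed query proteins against every genome of the panel."""
    params = params or ScoringParams()
    for sid, seq in seeds:
        if not seq:
            raise ValueError(f"seed {sid!r}: empty sequence")
    aligner = _aligner(params)
    seed_self = {sid: int(aligner.score(seq, seq)) for sid, seq in seeds}
    seed_kmers = {sid: _kmer_set(seq, params.kmer_size) for sid, seq in seeds}
    total_db = sum(g.length_aa for genome in panel for g in genome.genes)

    # seed x gene scores, computed once per (seed, gene) candidate
    cells: dict[str, dict[str, str | None]] = {sid: {} for sid, _ in seeds}
    srv_values: dict[str, dict[str, float]] = {sid: {} for sid, _ in seeds}
    for genome in panel:
        scores: dict[tuple[str, str], int] = {}
        gene_self: dict[str, int] = {}
        for gene in sorted(genome.genes, key=lambda g: g.locus_tag):
            gk = _kmer_set(gene.protein_seq, params.kmer_size)
            for sid, sseq in seeds:
                if params.prescreen and len(gk & seed_kmers[sid]) < params.min_shared_kmers:
                    continue
                raw = int(aligner.score(sseq, gene.protein_seq))
                _, ev = bits_and_evalue(raw, len(sseq), total_db, params)
                if ev <= params.evalue_cutoff:
                    scores[(sid, gene.locus_tag)] = raw
                    if gene.locus_tag not in gene_self:
                        gene_self[gene.locus_tag] = int(
                            aligner.score(gene.protein_seq, gene.protein_seq)
                        )
        for sid, _ in seeds:
            candidates = sorted(
                (locus for (s, locus) in scores if s == sid),
                key=lambda locus: (-scores[(sid, locus)], locus),
            )
            match = None
            if candidates:
                best_locus = candidates[0]
                # reciprocal: among all seeds, is sid the best for this gene?
                back = sorted(
                    (s for (s, locus) in scores if locus == best_locus),
                    key=lambda s: (-scores[(s, best_locus)], s),
                )
                srv_fwd = 100.0 * scores[(sid, best_locus)] / seed_self[sid]
                srv_rev = 100.0 * scores[(sid, best_locus)] / gene_self[best_locus]
                if back and back[0] == sid and srv_fwd > srv_threshold and srv_rev > srv_threshold:
                    match = best_locus
                    srv_values[sid][genome.genome_id] = round(min(srv_fwd, srv_rev), 1)
            cells[sid][genome.genome_id] = match

    matrix = PresenceMatrix(
        seeds=[sid for sid, _ in seeds],
        genomes=[g.genome_id for g in panel],
        cells=cells,
        srv_values=srv_values,
    )
    if operons:
        for name, members in operons.items():
            unknown = set(members) - set(matrix.seeds)
            if unknown:
                raise ValueError(f"operon {name!r} references unknown seeds {sorted(unknown)}")
            calls = {}
            for genome in matrix.genomes:
                n_present = sum(1 for m in members if matrix.present(m, genome))
                calls[genome] = (
                    "present" if n_present == len(members)
                    else "absent" if n_present == 0 else "partial"
                )
            matrix.operon_calls[name] = calls
    return matrix


def group_identity(
    sequences: list[str], params: ScoringParams | None = None
) -> float:
    """Minimum pairwise percent identity across homolog sequences.

    Identity is counted over global-alignment columns excluding terminal gap
    overhangs; internal gaps count as mismatched columns. With fewer than two
    sequences the quantity is undefined (ValueError).
    """
    if len(sequences) < 2:
        raise ValueError("group identity needs at least two sequences")
    params = params or ScoringParams()
    aligner = _aligner(params, mode="global")
    lowest = 100.0
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            aln = aligner.align(sequences[i], sequences[j])[0]
            ga, gb = str(aln[0]), str(aln[1])
            first = next(k for k in range(len(ga)) if ga[k] != "-" and gb[k] != "-")
            last = next(k for k in range(len(ga) - 1, -1, -1) if ga[k] != "-" and gb[k] != "-")
            span = range(first, last + 1)
            matches = sum(1 for k in span if ga[k] == gb[k])
            lowest = min(lowest, 100.0 * matches / len(span))
    return lowest


def gc_content(nt_seq: str) -> float:
    """G+C percentage over unambiguous bases, one decimal, round half-up."""
    seq = nt_seq.upper()
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("empty or all-N nucleotide sequence")
    pct = Decimal(100 * (counts["G"] + counts["C"])) / Decimal(denom)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class GCReport:
    locus_tag: str
    gc_percent: float
    genome_gc_percent: float
    delta: float


def gc_report(panel: list[Genome], loci: list[str]) -> list[GCReport]:
    """Per-locus G+C against the host genome background (all ORFs pooled)."""
    gene_index: dict[str, Gene] = {
        g.locus_tag: g for genome in panel for g in genome.genes
    }
    genome_gc: dict[str, float] = {}
    for genome in panel:
        pooled = "".join(g.nt_seq for g in genome.genes if g.nt_seq)
        if pooled:
            genome_gc[genome.genome_id] = gc_content(pooled)
    reports = []
    for locus in loci:
        gene = gene_index.get(locus)
        if gene is None or gene.nt_seq is None:
            continue
        gc = gc_content(gene.nt_seq)
        bg = genome_gc[gene.genome_id]
        reports.append(GCReport(locus, gc, bg, round(gc - bg, 1)))
    return reports


def presence_rows(matrix: PresenceMatrix) -> list[dict]:
    rows = []
    for seed in matrix.seeds:
        row = {"seed": seed}
        for genome in matrix.genomes:
            row[genome] = matrix.cells[seed][genome] or "-"
        rows.append(row)
    return rows
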