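"""In-process all-vs-all protein similarity.

Smith–Waterman local alignment under BLOSUM62 with affine gaps (a gap of
length k costs ``gap_open + k * gap_extend``, the BLAST convention), plus
Karlin–Altschul bit scores and E-values:

    bit = (lambda * S - ln K) / ln 2
    E   = m * n * 2**(-bit)

No effective-length correction is applied; m and n are the raw query and
database lengths. The E-value cutoff (default 1e-4) is permissive by design —
downstream orthology decisions are driven by the score ratio (SRV), not E.

A shared-k-mer prescreen (default: at least 3 shared 4-mers) skips the full
dynamic program for sequence pairs that cannot plausibly reach the cutoff;
it can be disabled for exhaustive runs.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import Genome

LN2 = math.log(2.0)


@dataclass
class ScoringParams:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267      # Karlin-Altschul lambda for gapped BLOSUM62 11/1
    k_const: float = 0.041  # Karlin-Altschul K for gapped BLOSUM62 11/1
    evalue_cutoff: float = 1e-4
    prescreen: bool = True
    kmer_size: int = 4
    min_shared_kmers: int = 3

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.lam <= 0 or self.k_const <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass
class RawHit:
    """One directed similarity result.

    ``raw_score`` is the optimal local alignment score; hits ingested from an
    external 12-column table carry only the bit score (``raw_score`` None),
    in which case downstream SRV normalization falls back to bit scores.
    """

    query: str
    subject: str
    raw_score: int | None
    bit_score: float
    evalue: float
    pident: float | None = None
    aln_length: int | None = None
    mismatch: int | None = None
    gapopen: int | None = None
    qstart: int | None = None
    qend: int | None = None
    sstart: int | None = None
    send: int | None = None
    known: bool = True

    @property
    def score(self) -> float:
        """Score used for SRV normalization and best-hit ranking."""
        return self.raw_score if self.raw_score is not None else self.bit_score

    def as_tabular(self) -> str:
        def fmt(x, default="0"):
            return default if x is None else str(x)

        return "\t".join([
            self.query, self.subject,
            fmt(self.pident, "0.0"), fmt(self.aln_length), fmt(self.mismatch),
            fmt(self.gapopen), fmt(self.qstart), fmt(self.qend),
            fmt(self.sstart), fmt(self.send),
            f"{self.evalue:.3g}", f"{self.bit_score:.1f}",
        ])


_ALIGNER_CACHE: dict[tuple, PairwiseAligner] = {}


def _aligner(params: ScoringParams, mode: str = "local") -> PairwiseAligner:
    key = (params.matrix_name, params.gap_open, params.gap_extend, mode)
    if key not in _ALIGNER_CACHE:
        aligner = PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
        # Biopython charges open_gap_score on the first gap residue; the BLAST
        # convention charges open + extend for a length-1 gap.
        aligner.open_gap_score = -(params.gap_open + params.gap_extend)
        aligner.extend_gap_score = -params.gap_extend
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def local_align(a: str, b: str, params: ScoringParams | None = None) -> int:
    """Optimal Smith–Waterman local alignment score (symmetric in a, b)."""
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    params = params or ScoringParams()
    return int(_aligner(params).score(a, b))


def bits_and_evalue(
    raw_score: float, m: int, n: int, params: ScoringParams | None = None
) -> tuple[float, float]:
    """Karlin–Altschul bit score and E-value for a raw score.

    m is the query length, n the total database length (raw, uncorrected).
    """
    if m <= 0 or n <= 0:
        raise ValueError("query and database lengths must be positive")
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    params = params or ScoringParams()
    bit = (params.lam * raw_score - math.log(params.k_const)) / LN2
    evalue = m * n * 2.0 ** (-bit)
    return bit, evalue


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


class HitTable:
    """Directed hits indexed for best-hit queries, plus self-hit raw scores.

    Self-hits are keyed by locus (a gene aligned to its own record), never to
    an identical-sequence paralog.
    """

    def __init__(self) -> None:
        self._hits: dict[tuple[str, str], RawHit] = {}
        self._by_query_genome: dict[str, dict[str, list[RawHit]]] = defaultdict(dict)
        self.genome_of: dict[str, str] = {}
        self.self_scores: dict[str, float] = {}

    def register_gene(self, locus_tag: str, genome_id: str) -> None:
        self.genome_of[locus_tag] = genome_id

    def add(self, hit: RawHit) -> None:
        self._hits[(hit.query, hit.subject)] = hit
        if hit.query == hit.subject:
            self.self_scores[hit.query] = hit.score
        subject_genome = self.genome_of.get(hit.subject)
        if subject_genome is not None:
            self._by_query_genome[hit.query].setdefault(subject_genome, []).append(hit)

    def get(self, query: str, subject: str) -> RawHit | None:
        return self._hits.get((query, subject))

    def self_score(self, locus_tag: str) -> float:
        if locus_tag not in self.self_scores:
            raise KeyError(f"missing self-hit for locus {locus_tag!r}")
        return self.self_scores[locus_tag]

    def hits_into(self, query: str, genome_id: str) -> list[RawHit]:
        return self._by_query_genome.get(query, {}).get(genome_id, [])

    def __iter__(self):
        return iter(self._hits.values())

    def __len__(self) -> int:
        return len(self._hits)

    @classmethod
    def from_hits(cls, panel: list[Genome], hits: list[RawHit]) -> "HitTable":
        """Index externally computed hits (e.g. read from a 12-column file)."""
        table = cls()
        for genome in panel:
            for gene in genome.genes:
                table.register_gene(gene.locus_tag, genome.genome_id)
        for hit in hits:
            hit.known = hit.query in table.genome_of and hit.subject in table.genome_of
            table.add(hit)
        return table


def all_vs_all(panel: list[Genome], params: ScoringParams | None = None) -> HitTable:
    """All-versus-all gene-to-gene comparison across a strain panel.

    Every directed pair whose E-value passes the cutoff is retained; the
    self-hit of every gene is always retained regardless of E. Raw scores are
    symmetric, so each unordered pair is aligned once.
    """
    params = params or ScoringParams()
    if not panel:
        raise ValueError("panel must contain at least one genome")
    genes = []
    for genome in sorted(panel, key=lambda g: g.genome_id):
        for gene in sorted(genome.genes, key=lambda g: g.locus_tag):
            genes.append(gene)

    table = HitTable()
    for gene in genes:
        table.register_gene(gene.locus_tag, gene.genome_id)

    total_db = sum(g.length_aa for g in genes)
    aligner = _aligner(params)

    # self-hits first (always retained)
    for gene in genes:
        raw = int(aligner.score(gene.protein_seq, gene.protein_seq))
        bit, ev = bits_and_evalue(raw, gene.length_aa, total_db, params)
        table.add(RawHit(gene.locus_tag, gene.locus_tag, raw, bit, ev))

    candidate_pairs = _candidate_pairs(genes, params)
    for i, j in candidate_pairs:
        a, b = genes[i], genes[j]
        raw = int(aligner.score(a.protein_seq, b.protein_seq))
        bit_ab, ev_ab = bits_and_evalue(raw, a.length_aa, total_db, params)
        if ev_ab <= params.evalue_cutoff:
            table.add(RawHit(a.locus_tag, b.locus_tag, raw, bit_ab, ev_ab))
        bit_ba, ev_ba = bits_and_evalue(raw, b.length_aa, total_db, params)
        if ev_ba <= params.evalue_cutoff:
            table.add(RawHit(b.locus_tag, a.locus_tag, raw, bit_ba, ev_ba))
    return table


def _candidate_pairs(genes: list, params: ScoringParams) -> list[tuple[int, int]]:
    """Unordered index pairs to align fully, after the optional prescreen."""
    n = len(genes)
    if not params.prescreen:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    k = params.kmer_size
    index: dict[str, list[int]] = defaultdict(list)
    for i, gene in enumerate(genes):
        for kmer in _kmer_set(gene.protein_seq, k):
            index[kmer].append(i)
    shared: dict[tuple[int, int], int] = defaultdict(int)
    for members in index.values():
        if len(members) < 2:
            continue
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                shared[(members[x], members[y])] += 1
    return sorted(p for p, c in shared.items() if c >= params.min_shared_kmers)


def search_against(
    queries: list, targets: list[tuple[str, str]], params: ScoringParams | None = None
) -> dict[str, float]:
    """Best E-value per query against a target database (for ORFan calls).

    ``queries`` are Gene objects; ``targets`` are (id, protein_seq) pairs.
    Returns locus_tag -> min E-value over targets with E <= cutoff; queries
    with no qualifying hit are absent from the result.
    """
    params = params or ScoringParams()
    total_db = sum(len(s) for _, s in targets)
    if total_db == 0:
        raise ValueError("empty target database")
    aligner = _aligner(params)
    k = params.kmer_size
    target_kmers = [_kmer_set(seq, k) for _, seq in targets]
    best: dict[str, float] = {}
    for gene in queries:
        qk = _kmer_set(gene.protein_seq, k)
        for (tid, tseq), tk in zip(targets, target_kmers):
            if params.prescreen and len(qk & tk) < params.min_shared_kmers:
                continue
            raw = int(aligner.score(gene.protein_seq, tseq))
            _, ev = bits_and_evalue(raw, gene.length_aa, total_db, params)
            if ev <= params.evalue_cutoff:
                if gene.locus_tag not in best or ev < best[gene.locus_tag]:
                    best[gene.locus_tag] = ev
    return best


def alignment_details(a: str, b: str, params: ScoringParams | None = None) -> dict:
    """Traceback-level detail (identity, coordinates) for one local alignment.

    Used only when emitting full 12-column hit tables; scores elsewhere come
    from the cheaper score-only routine.
    """
    params = params or ScoringParams()
    aln = _aligner(params).align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    mismatches = sum(1 for x, y in zip(ga, gb) if x != y and x != "-" and y != "-")
    gapopens = 0
    for row in (ga, gb):
        in_gap = False
        for c in row:
            if c == "-" and not in_gap:
                gapopens += 1
            in_gap = c == "-"
    qstart, qend = aln.aligned[0][0][0] + 1, aln.aligned[0][-1][1]
    sstart, send = aln.aligned[1][0][0] + 1, aln.aligned[1][-1][1]
    length = len(ga)
    return {
        "pident": round(100.0 * matches / length, 1) if length else 0.0,
        "length": length,
        "mismatch": mismatches,
        "gapopen": gapopens,
        "qstart": qstart, "qend": qend, "sstart": sstart, "send": send,
    }
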