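"""On-disk artifacts: proteome/nucleotide FASTA, tabular hit files, TSV reports.

All readers validate eagerly and all writers emit deterministically sorted,
'#'-headered TSV so that two runs on the same input are byte-identical.
Coordinates in emitted hit tables are 1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTN")


@dataclass
class Gene:
    """One ORF: its locus tag, host strain and sequences.

    ``nt_seq`` is optional; when present but not a positive multiple of three
    the gene is flagged ``fragmentary`` (common in draft assemblies) rather
    than rejected.
    """

    locus_tag: str
    genome_id: str
    protein_seq: str
    nt_seq: str | None = None
    description: str = ""
    fragmentary: bool = False

    def __post_init__(self) -> None:
        if not self.protein_seq:
            raise ValueError(f"gene {self.locus_tag!r}: empty protein sequence")
        if self.nt_seq is not None and (len(self.nt_seq) == 0 or len(self.nt_seq) % 3 != 0):
            self.fragmentary = True

    @property
    def length_aa(self) -> int:
        return len(self.protein_seq)


@dataclass
class Genome:
    """An ordered strain proteome with a unique ``genome_id``."""

    genome_id: str
    genes: list[Gene] = field(default_factory=list)
    size_mbp: float | None = None

    def __post_init__(self) -> None:
        self._by_tag = {}
        for g in self.genes:
            if g.locus_tag in self._by_tag:
                raise ValueError(
                    f"genome {self.genome_id!r}: duplicate locus_tag {g.locus_tag!r}"
                )
            self._by_tag[g.locus_tag] = g

    @property
    def n_orfs(self) -> int:
        return len(self.genes)

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_tag

    def __getitem__(self, locus_tag: str) -> Gene:
        return self._by_tag[locus_tag]


def read_proteome(path: str | os.PathLike, genome_id: str) -> Genome:
    """Read a protein FASTA into a :class:`Genome`.

    The first whitespace-delimited header token becomes the locus tag; the
    remainder is kept as a free-text description. A single terminal ``*``
    (stop) is stripped. Residues outside the 20 canonical amino acids plus X
    are rejected with the offending record and position named.
    """
    genes: list[Gene] = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        for i, c in enumerate(seq):
            if c not in AA_ALPHABET:
                raise ValueError(
                    f"record {rec.id!r}: invalid amino-acid character {c!r} at position {i + 1}"
                )
        genes.append(
            Gene(
                locus_tag=rec.id,
                genome_id=genome_id,
                protein_seq=seq,
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not genes:
        raise ValueError(f"no FASTA records in {os.fspath(path)!r}")
    return Genome(genome_id=genome_id, genes=genes)


def attach_nucleotides(genome: Genome, path: str | os.PathLike) -> Genome:
    """Attach per-ORF nucleotide sequences (matched by locus tag) in place."""
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id not in genome:
            continue
        seq = str(rec.seq).upper()
        bad = set(seq) - NT_ALPHABET
        if bad:
            raise ValueError(f"record {rec.id!r}: invalid nucleotide characters {sorted(bad)}")
        gene = genome[rec.id]
        gene.nt_seq = seq
        gene.fragmentary = len(seq) == 0 or len(seq) % 3 != 0
    return genome


def write_fasta(records: list[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write ``(id, sequence)`` pairs as single-line FASTA (deterministic)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_proteomes(panel: list[Genome], out_dir: str | os.PathLike) -> dict[str, str]:
    """One ``<genome_id>.faa`` per genome; returns genome_id -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for genome in panel:
        p = os.path.join(os.fspath(out_dir), f"{genome.genome_id}.faa")
        write_fasta([(g.locus_tag, g.protein_seq) for g in genome.genes], p)
        paths[genome.genome_id] = p
    return paths


# --- 12-column tabular hit format (the de-facto "outfmt 6" dialect) ---------

HIT_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_hit_table(path: str | os.PathLike, known_loci: set[str] | None = None):
    """Parse a 12-column tab-separated hit file into :class:`~srvpan.similarity.RawHit`.

    Rows referencing loci outside ``known_loci`` (when given) are retained but
    flagged ``known=False``. Malformed rows raise with their line number.
    """
    from .similarity import RawHit  # local import: avoid cycle

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{os.fspath(path)}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hit = RawHit(
                    query=fields[0],
                    subject=fields[1],
                    raw_score=None,
                    bit_score=float(fields[11]),
                    evalue=float(fields[10]),
                    pident=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                )
            except ValueError as exc:
                raise ValueError(f"{os.fspath(path)}: line {lineno}: {exc}") from exc
            if known_loci is not None:
                hit.known = hit.query in known_loci and hit.subject in known_loci
            hits.append(hit)
    return hits


def write_hit_table(hits, path: str | os.PathLike) -> None:
    """Emit hits in the 12-column format, sorted by (query, subject)."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.query, h.subject)):
            fh.write(h.as_tabular() + "\n")


# --- generic '#'-headered TSV tables ----------------------------------------

def write_table(rows: list[dict], columns: list[str], path: str | os.PathLike) -> None:
    """Write dict rows as TSV with a '#'-prefixed header, in given row order."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_table(path: str | os.PathLike) -> list[dict]:
    """Read back a '#'-headered TSV as a list of string-valued dict rows."""
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{os.fspath(path)}: missing '#'-prefixed header line")
        columns = header[1:].split("\t")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(f"{os.fspath(path)}: row/column count mismatch")
            rows.append(dict(zip(columns, fields)))
    return rows


def write_classification_table(labels: dict[str, tuple[str, str]], path) -> None:
    """Per-gene class table: rows sorted by (genome_id, locus_tag).

    ``labels`` maps locus_tag -> (genome_id, class_label).
    """
    rows = [
        {"genome_id": gid, "locus_tag": tag, "class": label}
        for tag, (gid, label) in labels.items()
    ]
    rows.sort(key=lambda r: (r["genome_id"], r["locus_tag"]))
    write_table(rows, ["genome_id", "locus_tag", "class"], path)


def read_classification_table(path) -> dict[str, tuple[str, str]]:
    return {
        r["locus_tag"]: (r["genome_id"], r["class"]) for r in read_table(path)
    }
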