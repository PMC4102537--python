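"""Classical (Sec-pathway) secretome calls and core/dispensable partitioning.

The built-in scorer is a deterministic heuristic for the tripartite
N-terminal signal peptide of Gram-positive bacteria: a positively charged
n-region, a hydrophobic h-region, and a small-residue c-region cleavage
pattern. It is explicitly a stand-in for a trained predictor — the scorer is
a plug-in (precomputed per-locus scores are accepted via
:func:`calls_from_scores`) and the partition logic is the analysis of
interest.

Score = 0.25 * charge + 0.5 * hydrophobicity + 0.25 * cleavage, each
component min-max normalized to [0, 1] over the first 45 residues:

* charge: net (K+R) - (D+E) within residues 1-7, normalized over [0, 3];
* hydrophobicity: maximal 8-residue mean Kyte-Doolittle value among windows
  within residues 3-25, normalized over [2.0, 3.8] (a genuine h-region is
  strongly hydrophobic; typical globular windows fall below this range);
* cleavage: 1 if an A-X-A pattern (G or S allowed in place of A) ends at some
  position 15-45.

Proteins shorter than 30 residues score 0 (not secreted), without error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Genome
from .orthology import OrthologGroup
from .pangenome import PanClassification

DEFAULT_CUTOFF = 0.45

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

_SMALL = frozenset("AGS")
_CHARGE_RANGE = (0.0, 3.0)
_HYDRO_RANGE = (2.0, 3.8)


@dataclass
class SecretionCall:
    locus_tag: str
    score: float
    secreted: bool
    cleavage_pos: int | None = None


def _minmax(value: float, lo: float, hi: float) -> float:
    return min(1.0, max(0.0, (value - lo) / (hi - lo)))


def sp_score(protein_seq: str, locus_tag: str = "", cutoff: float = DEFAULT_CUTOFF) -> SecretionCall:
    """Score the first 45 residues for a classical N-terminal signal peptide."""
    seq = protein_seq.upper()
    if len(seq) < 30:
        return SecretionCall(locus_tag=locus_tag, score=0.0, secreted=False)
    head = seq[:45]

    n_region = head[:7]
    charge = sum(1 for c in n_region if c in "KR") - sum(1 for c in n_region if c in "DE")
    charge_comp = _minmax(float(charge), *_CHARGE_RANGE)

    # 8-mer windows fully inside residues 3..25 (1-based)
    window_means = [
        sum(KYTE_DOOLITTLE.get(c, 0.0) for c in head[start:start + 8]) / 8.0
        for start in range(2, min(18, len(head) - 7))
    ]
    hydro_comp = _minmax(max(window_means), *_HYDRO_RANGE) if window_means else 0.0

    cleavage_pos = None
    for p in range(15, min(45, len(head)) + 1):  # p = 1-based end position of A-X-A
        if head[p - 3] in _SMALL and head[p - 1] in _SMALL:
            cleavage_pos = p
            break
    cleavage_comp = 1.0 if cleavage_pos is not None else 0.0

    score = 0.25 * charge_comp + 0.5 * hydro_comp + 0.25 * cleavage_comp
    return SecretionCall(
        locus_tag=locus_tag,
        score=round(score, 6),
        secreted=score >= cutoff,
        cleavage_pos=cleavage_pos,
    )


def score_panel(panel: list[Genome], cutoff: float = DEFAULT_CUTOFF) -> dict[str, SecretionCall]:
    return {
        gene.locus_tag: sp_score(gene.protein_seq, gene.locus_tag, cutoff)
        for genome in panel
        for gene in genome.genes
    }


def calls_from_scores(scores: dict[str, float], cutoff: float = DEFAULT_CUTOFF) -> dict[str, SecretionCall]:
    """Wrap externally computed per-locus scores (plug-in predictor output)."""
    return {
        locus: SecretionCall(locus_tag=locus, score=s, secreted=s >= cutoff)
        for locus, s in scores.items()
    }


@dataclass
class SecretomePartition:
    secretome_groups: list[str]
    core_secretome: list[str]
    dispensable_secretome: list[str]
    per_genome_secreted: dict[str, int] = field(default_factory=dict)
    member_gene_tally: int = 0          # total member genes across secretome groups

    @property
    def size(self) -> int:
        return len(self.secretome_groups)


def pan_secretome(
    panel: list[Genome],
    groups: list[OrthologGroup],
    classification: PanClassification,
    calls: dict[str, SecretionCall],
    cutoff: float = DEFAULT_CUTOFF,
) -> SecretomePartition:
    """Partition secretome groups into core and dispensable.

    A group enters the secretome when the majority of its members are called
    secreted (ties count as secreted); it inherits core/dispensable status
    from the pan-genome classification. Per-genome totals count individual
    secreted proteins (per-gene calls), independent of grouping.
    """
    missing = [
        gene.locus_tag
        for genome in panel for gene in genome.genes
        if gene.locus_tag not in calls
    ]
    if missing:
        raise ValueError(f"secretion calls missing for {len(missing)} genes, e.g. {missing[0]!r}")

    core_ids = set(classification.core_groups)
    secretome, core_sec, disp_sec = [], [], []
    tally = 0
    for group in groups:
        flags = [calls[locus].secreted for locus in group.members.values()]
        n_secreted = sum(flags)
        if 2 * n_secreted >= len(flags) and n_secreted > 0:
            secretome.append(group.group_id)
            tally += len(flags)
            if group.group_id in core_ids:
                core_sec.append(group.group_id)
            else:
                disp_sec.append(group.group_id)

    per_genome = {
        genome.genome_id: sum(
            1 for gene in genome.genes if calls[gene.locus_tag].secreted
        )
        for genome in panel
    }
    return SecretomePartition(
        secretome_groups=sorted(secretome),
        core_secretome=sorted(core_sec),
        dispensable_secretome=sorted(disp_sec),
        per_genome_secreted=per_genome,
        member_gene_tally=tally,
    )
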