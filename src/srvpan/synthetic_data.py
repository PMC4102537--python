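"""Synthetic strain panels with known ground truth.

A panel of ~13 strains is derived from one ancestral proteome by evolution
along a known strain tree: per-branch Bernoulli gene loss, strain-specific
(terminal-branch) Poisson gene gain of novel random genes, and per-site
residue substitution biased toward high-BLOSUM62 exchanges so that homologs
stay detectable at the stated rates. A stated fraction of ancestral genes
carries a planted N-terminal signal peptide (constructed to satisfy all
three components of the secretion heuristic), and a 4-gene pilus-like operon
with planted signal peptides and a distinct (lower) G+C content is inserted
into a designated subset of strains — the stand-in for laterally transferred
surface-protein loci. Nucleotide sequences are back-generated with codon
choices biased toward a per-gene G+C target.

Everything is reproducible from ``rng_seed``. The emitted truth (per-gene
class and secretion labels, operon placements, the generating tree, the
ancestral-gene -> per-strain locus map, and an outgroup database containing
diverged copies of the ancestral genes only) is the oracle for pipeline
tests: gained and operon genes are the true ORFans.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .genome_io import Gene, Genome, write_table
from .phylo import TreeNode

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# approximate bacterial proteome residue frequencies
_AA_FREQS = np.array([
    0.089, 0.012, 0.054, 0.060, 0.038, 0.078, 0.021, 0.059, 0.046, 0.100,
    0.026, 0.040, 0.043, 0.039, 0.055, 0.058, 0.054, 0.073, 0.013, 0.032,
])
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

SP_PREFIX_LEN = 18  # planted signal peptides are protected from substitution


@dataclass
class SimParams:
    n_strains: int = 13
    n_ancestral_genes: int = 100
    gene_length_range: tuple[int, int] = (80, 400)
    loss_prob: float = 0.02
    gain_rate: float = 3.0
    sub_rate: float = 0.01
    sp_fraction: float = 0.1
    operon_strains: list[str] | None = None    # default: strains 1, 4, 7, 10
    reference: str | None = None               # default: first strain
    genome_gc: float = 0.47
    operon_gc: float = 0.44
    tree: TreeNode | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_prob", "sub_rate", "sp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gain_rate < 0:
            raise ValueError("gain_rate must be non-negative")
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")

    def strain_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_strains)]


@dataclass
class SyntheticTruth:
    class_labels: dict[str, str]               # locus -> core|dispensable|unique
    secretion_labels: dict[str, bool]
    orfan_loci: set[str]
    operon_loci: dict[str, list[str]]          # strain -> planted loci
    tree: TreeNode
    ortholog_map: dict[str, dict[str, str]]    # ancestral id -> strain -> locus
    seed_proteins: list[tuple[str, str]]       # operon query seeds
    outgroup_db: list[tuple[str, str]]
    reference: str = ""


def _random_tree(strains: list[str], rng: np.random.Generator) -> TreeNode:
    nodes = [TreeNode(name=s, length=float(rng.uniform(0.5, 1.5))) for s in strains]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(
            length=float(rng.uniform(0.5, 1.5)),
            children=[nodes[i], nodes[j]],
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes)


def _validate_tree(tree: TreeNode, strains: list[str]) -> None:
    if sorted(tree.leaves()) != sorted(strains):
        raise ValueError("tree leaf set must equal the strain panel")


_SUB_DISTS: dict[str, tuple[str, np.ndarray]] | None = None


def _substitution_dists() -> dict[str, tuple[str, np.ndarray]]:
    """Per-residue replacement distributions favoring high-BLOSUM62 exchanges."""
    global _SUB_DISTS
    if _SUB_DISTS is None:
        blosum = substitution_matrices.load("BLOSUM62")
        dists = {}
        for a in AMINO_ACIDS:
            others = [b for b in AMINO_ACIDS if b != a]
            weights = np.array([np.exp(0.6 * blosum[a, b]) for b in others])
            dists[a] = ("".join(others), weights / weights.sum())
        _SUB_DISTS = dists
    return _SUB_DISTS


def _random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=_AA_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _signal_peptide(rng: np.random.Generator) -> str:
    h_region = "".join(rng.choice(list("LIV"), size=12))
    x = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
    return "MKK" + h_region + "A" + x + "A"


def _mutate(seq: str, p: float, rng: np.random.Generator, protect_prefix: int = 0) -> str:
    if p <= 0:
        return seq
    dists = _substitution_dists()
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in hits:
        if i < protect_prefix:
            continue
        a = chars[i]
        if a not in dists:
            continue
        alphabet, weights = dists[a]
        chars[i] = alphabet[int(rng.choice(len(alphabet), p=weights))]
    return "".join(chars)


_CODON_CUMWEIGHTS: dict[tuple[str, float], np.ndarray] = {}


def _codon_cumweights(aa: str, target_gc: float) -> np.ndarray:
    key = (aa, target_gc)
    if key not in _CODON_CUMWEIGHTS:
        options = _CODONS.get(aa, _CODONS["A"])
        gcs = np.array([sum(c in "GC" for c in codon) / 3.0 for codon in options])
        weights = np.exp(-8.0 * np.abs(gcs - target_gc))
        _CODON_CUMWEIGHTS[key] = np.cumsum(weights / weights.sum())
    return _CODON_CUMWEIGHTS[key]


def _back_translate(seq: str, target_gc: float, rng: np.random.Generator) -> str:
    u = rng.random(len(seq))
    codons = []
    for aa, x in zip(seq, u):
        options = _CODONS.get(aa, _CODONS["A"])  # X falls back to Ala codons
        cumw = _codon_cumweights(aa, target_gc)
        codons.append(options[int(np.searchsorted(cumw, x))])
    return "".join(codons)


def simulate_panel(params: SimParams) -> tuple[list[Genome], SyntheticTruth]:
    """Evolve a strain panel from one ancestral proteome; return it with truth."""
    rng = np.random.default_rng(params.rng_seed)
    strains = params.strain_names()
    reference = params.reference or strains[0]
    if reference not in strains:
        raise ValueError(f"reference {reference!r} not among strains")
    operon_strains = params.operon_strains
    if operon_strains is None:
        picks = [0, 3, 6, 9]
        operon_strains = [strains[i % len(strains)] for i in picks]
        operon_strains = sorted(set(operon_strains))
    unknown = set(operon_strains) - set(strains)
    if unknown:
        raise ValueError(f"operon_strains not in panel: {sorted(unknown)}")

    tree = params.tree or _random_tree(strains, rng)
    _validate_tree(tree, strains)

    # ancestral proteome
    lo, hi = params.gene_length_range
    n_sp = int(round(params.sp_fraction * params.n_ancestral_genes))
    sp_genes = set(rng.choice(params.n_ancestral_genes, size=n_sp, replace=False).tolist())
    ancestral: list[tuple[str, str, bool]] = []
    for i in range(params.n_ancestral_genes):
        anc_id = f"g{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        if i in sp_genes:
            seq = _signal_peptide(rng) + _random_protein(max(length - SP_PREFIX_LEN, 20), rng)
        else:
            seq = "M" + _random_protein(length - 1, rng)
        ancestral.append((anc_id, seq, i in sp_genes))

    # 4-gene pilus-like operon, signal-peptided, distinct G+C
    operon_anc = []
    for i in range(4):
        length = int(rng.integers(250, 400))
        operon_anc.append((
            f"op{i + 1}",
            _signal_peptide(rng) + _random_protein(length - SP_PREFIX_LEN, rng),
        ))

    # evolve gene content + sequences along the tree
    leaf_genes: dict[str, list[tuple[str, str, bool]]] = {}

    def evolve(node: TreeNode, genes: list[tuple[str, str, bool]]) -> None:
        p_sub = min(0.95, params.sub_rate * node.length)
        survived = []
        for anc_id, seq, has_sp in genes:
            if rng.random() < params.loss_prob:
                continue
            protect = SP_PREFIX_LEN if has_sp else 0
            survived.append((anc_id, _mutate(seq, p_sub, rng, protect), has_sp))
        if node.is_leaf():
            leaf_genes[node.name] = survived
        else:
            for child in node.children:
                evolve(child, list(survived))

    for child in tree.children:
        evolve(child, list(ancestral))

    # assemble genomes: retained ancestral genes, planted operon, gained genes
    panel: list[Genome] = []
    ortholog_map: dict[str, dict[str, str]] = {a: {} for a, _, _ in ancestral}
    for oid, _ in operon_anc:
        ortholog_map[oid] = {}
    secretion: dict[str, bool] = {}
    operon_loci: dict[str, list[str]] = {s: [] for s in strains}
    gained: set[str] = set()
    presence: dict[str, set[str]] = {a: set() for a, _, _ in ancestral}

    for strain in strains:
        records: list[tuple[str, str, bool, str, float]] = []  # (anc, seq, sp, kind, gc)
        for anc_id, seq, has_sp in leaf_genes[strain]:
            records.append((anc_id, seq, has_sp, "ancestral", params.genome_gc))
            presence[anc_id].add(strain)
        if strain in operon_strains:
            for oid, seq in operon_anc:
                seq = _mutate(seq, 0.005, rng, SP_PREFIX_LEN)
                records.append((oid, seq, True, "operon", params.operon_gc))
        n_gain = int(rng.poisson(params.gain_rate))
        for k in range(n_gain):
            length = int(rng.integers(lo, hi + 1))
            seq = "M" + _random_protein(length - 1, rng)
            records.append((f"{strain}.n{k + 1}", seq, False, "gained", params.genome_gc))

        genes = []
        for idx, (anc_id, seq, has_sp, kind, gc) in enumerate(records):
            locus = f"{strain}_{idx + 1:04d}"
            genes.append(Gene(
                locus_tag=locus,
                genome_id=strain,
                protein_seq=seq,
                nt_seq=_back_translate(seq, gc, rng),
            ))
            secretion[locus] = has_sp
            if kind in ("ancestral", "operon"):
                ortholog_map[anc_id][strain] = locus
            if kind == "operon":
                operon_loci[strain].append(locus)
            if kind == "gained":
                gained.add(locus)
        panel.append(Genome(genome_id=strain, genes=genes))

    # truth labels from realized presence patterns
    class_labels: dict[str, str] = {}
    for anc_id, strain_map in ortholog_map.items():
        n_present = len(strain_map)
        label = (
            "core" if n_present == params.n_strains
            else "unique" if n_present == 1 else "dispensable"
        )
        for locus in strain_map.values():
            class_labels[locus] = label
    for locus in gained:
        class_labels[locus] = "unique"

    orfans = set(gained)
    for loci in operon_loci.values():
        orfans.update(loci)

    outgroup_db = [
        (f"OUT_{anc_id}", _mutate(seq, 0.05, rng, SP_PREFIX_LEN if has_sp else 0))
        for anc_id, seq, has_sp in ancestral
    ]

    truth = SyntheticTruth(
        class_labels=class_labels,
        secretion_labels=secretion,
        orfan_loci=orfans,
        operon_loci={s: loci for s, loci in operon_loci.items() if loci},
        tree=tree,
        ortholog_map=ortholog_map,
        seed_proteins=list(operon_anc),
        outgroup_db=outgroup_db,
        reference=reference,
    )
    return panel, truth


def truth_report(truth: SyntheticTruth, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write machine-readable truth tables; returns name -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    rows = []
    for anc_id in sorted(truth.ortholog_map):
        for strain in sorted(truth.ortholog_map[anc_id]):
            locus = truth.ortholog_map[anc_id][strain]
            rows.append({
                "ancestral_id": anc_id, "genome_id": strain, "locus_tag": locus,
                "class": truth.class_labels[locus],
                "secreted": int(truth.secretion_labels[locus]),
                "orfan": int(locus in truth.orfan_loci),
            })
    seen = {r["locus_tag"] for r in rows}
    for locus, label in sorted(truth.class_labels.items()):
        if locus in seen:
            continue
        rows.append({
            "ancestral_id": "-", "genome_id": locus.split("_")[0], "locus_tag": locus,
            "class": label,
            "secreted": int(truth.secretion_labels[locus]),
            "orfan": int(locus in truth.orfan_loci),
        })
    rows.sort(key=lambda r: (r["genome_id"], r["locus_tag"]))
    p = os.path.join(os.fspath(out_dir), "truth_genes.tsv")
    write_table(rows, ["ancestral_id", "genome_id", "locus_tag", "class", "secreted", "orfan"], p)
    paths["genes"] = p

    p = os.path.join(os.fspath(out_dir), "truth_tree.nwk")
    with open(p, "w") as fh:
        fh.write(truth.tree.newick() + "\n")
    paths["tree"] = p
    return paths
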