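"""Pan/core/dispensable/unique/ORFan partitioning, development curves, Heap's law.

The pan-genome is the union of all ortholog groups; the core has a member in
every genome; the dispensable genome is the remainder (and contains the
unique, single-genome groups). ORFan genes additionally lack any qualifying
hit (E-value cutoff only — SRV normalization is defined for within-panel
self-hits and is not applied) against an outgroup protein database.

Openness follows Heap's law: fitting median pan size over permuted genome
orderings to kappa * N**gamma; alpha = 1 - gamma, with alpha < 1 read as an
open pan-genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .genome_io import Genome
from .orthology import OrthologGroup
from .similarity import ScoringParams, search_against


@dataclass
class PanClassification:
    n_genomes: int
    pan_groups: list[str]
    core_groups: list[str]
    dispensable_groups: list[str]
    unique_groups: list[str]
    orfan_loci: set[str] | None          # None = undefined (no outgroup database)
    per_genome_unique: dict[str, int] = field(default_factory=dict)
    per_genome_orfan: dict[str, int] = field(default_factory=dict)
    gene_labels: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def pan_size(self) -> int:
        return len(self.pan_groups)

    @property
    def core_size(self) -> int:
        return len(self.core_groups)

    @property
    def dispensable_size(self) -> int:
        return len(self.dispensable_groups)

    @property
    def unique_size(self) -> int:
        return len(self.unique_groups)


def classify(
    panel: list[Genome],
    groups: list[OrthologGroup],
    outgroup_db: list[tuple[str, str]] | None = None,
    params: ScoringParams | None = None,
) -> PanClassification:
    """Partition ortholog groups and call ORFan loci.

    ``outgroup_db`` is a list of (id, protein_seq) records; when None, ORFan
    status is undefined (reported as None, not as the empty set).
    """
    n_genomes = len(panel)
    pan, core, dispensable, unique = [], [], [], []
    per_genome_unique = {g.genome_id: 0 for g in panel}
    gene_labels: dict[str, tuple[str, str]] = {}

    for group in groups:
        pan.append(group.group_id)
        if group.size == n_genomes:
            core.append(group.group_id)
            label = "core"
        else:
            dispensable.append(group.group_id)
            label = "dispensable"
            if group.size == 1:
                unique.append(group.group_id)
                label = "unique"
                per_genome_unique[next(iter(group.members))] += 1
        for genome_id, locus in group.members.items():
            gene_labels[locus] = (genome_id, label)

    orfan_loci: set[str] | None = None
    per_genome_orfan: dict[str, int] = {}
    if outgroup_db is not None:
        params = params or ScoringParams()
        all_genes = [gene for genome in panel for gene in genome.genes]
        matched = search_against(all_genes, outgroup_db, params)
        orfan_loci = {g.locus_tag for g in all_genes if g.locus_tag not in matched}
        per_genome_orfan = {g.genome_id: 0 for g in panel}
        for genome in panel:
            per_genome_orfan[genome.genome_id] = sum(
                1 for gene in genome.genes if gene.locus_tag in orfan_loci
            )

    return PanClassification(
        n_genomes=n_genomes,
        pan_groups=sorted(pan),
        core_groups=sorted(core),
        dispensable_groups=sorted(dispensable),
        unique_groups=sorted(unique),
        orfan_loci=orfan_loci,
        per_genome_unique=per_genome_unique,
        per_genome_orfan=per_genome_orfan,
        gene_labels=gene_labels,
    )


@dataclass
class DevelopmentCurve:
    """Pan/core trajectories over sampled genome orderings.

    ``pan`` and ``core`` are (n_permutations, n_genomes) arrays; column N-1
    holds sizes after including the first N genomes of each ordering.
    """

    pan: np.ndarray
    core: np.ndarray
    orderings: list[list[str]]
    rng_seed: int

    @property
    def n_genomes(self) -> int:
        return self.pan.shape[1]

    @property
    def n_permutations(self) -> int:
        return self.pan.shape[0]

    def median_pan(self) -> np.ndarray:
        return np.median(self.pan, axis=0)

    def median_core(self) -> np.ndarray:
        return np.median(self.core, axis=0)


def development_curve(
    panel: list[Genome],
    groups: list[OrthologGroup],
    n_permutations: int = 100,
    rng_seed: int = 0,
) -> DevelopmentCurve:
    """Sample genome orderings and accumulate pan (union) / core (intersection)."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    genome_ids = [g.genome_id for g in panel]
    membership = {
        gid: frozenset(gr.group_id for gr in groups if gid in gr.members)
        for gid in genome_ids
    }
    rng = np.random.default_rng(rng_seed)
    n = len(genome_ids)
    pan = np.zeros((n_permutations, n), dtype=int)
    core = np.zeros((n_permutations, n), dtype=int)
    orderings = []
    for p in range(n_permutations):
        order = [genome_ids[i] for i in rng.permutation(n)]
        orderings.append(order)
        acc_pan: set = set()
        acc_core: frozenset | None = None
        for i, gid in enumerate(order):
            acc_pan |= membership[gid]
            acc_core = membership[gid] if acc_core is None else acc_core & membership[gid]
            pan[p, i] = len(acc_pan)
            core[p, i] = len(acc_core)
    return DevelopmentCurve(pan=pan, core=core, orderings=orderings, rng_seed=rng_seed)


@dataclass
class HeapFit:
    kappa: float
    gamma: float
    alpha: float
    rss: float
    open_pangenome: bool
    alt_alpha_new_genes: float | None = None

    def __post_init__(self) -> None:
        assert abs((self.alpha + self.gamma) - 1.0) < 1e-9


def heap_fit(curve: DevelopmentCurve) -> HeapFit:
    """Nonlinear least squares of median pan(N) against kappa * N**gamma.

    Initial values come from a log-log linear regression; parameter
    convergence tolerance 1e-10. Also fits the secondary new-genes-per-genome
    ~ N**(-alpha) regression for comparison (not the headline number).
    """
    y = curve.median_pan()
    n_points = len(y)
    if n_points < 3:
        raise ValueError("heap_fit needs at least 3 genome counts")
    if np.any(y <= 0):
        raise ValueError("pan sizes must be positive")
    N = np.arange(1, n_points + 1, dtype=float)

    slope, intercept = np.polyfit(np.log(N), np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, _ = curve_fit(
        lambda x, kappa, gamma: kappa * x ** gamma, N, y, p0=p0, xtol=1e-10, ftol=1e-10
    )
    kappa, gamma = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - kappa * N ** gamma) ** 2))
    alpha = 1.0 - gamma

    alt_alpha = None
    new_genes = np.diff(np.median(curve.pan, axis=0))
    mask = new_genes > 0
    if mask.sum() >= 2:
        n_new = N[1:][mask]
        alt_slope, _ = np.polyfit(np.log(n_new), np.log(new_genes[mask]), 1)
        alt_alpha = float(-alt_slope)

    return HeapFit(
        kappa=kappa,
        gamma=gamma,
        alpha=alpha,
        rss=rss,
        open_pangenome=alpha < 1.0,
        alt_alpha_new_genes=alt_alpha,
    )


def curve_rows(curve: DevelopmentCurve) -> list[dict]:
    """Flat rows (N, ordering index, pan, core) for the curve TSV."""
    rows = []
    for p in range(curve.n_permutations):
        for i in range(curve.n_genomes):
            rows.append({
                "N": i + 1,
                "ordering": p,
                "pan": int(curve.pan[p, i]),
                "core": int(curve.core[p, i]),
            })
    return rows
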