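"""End-to-end orchestration: similarity -> orthology -> pan-genome ->
secretome -> phylogeny -> surface screen, with deterministic report output.

A run is described by a RunConfig (plain key: value YAML). Identical config
plus seed yields byte-identical outputs. Any stage failure aborts with the
stage name and cause, and partial outputs are removed.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .genome_io import (
    Genome,
    attach_nucleotides,
    read_proteome,
    write_classification_table,
    write_table,
)
from .orthology import DEFAULT_SRV_THRESHOLD, build_groups, group_table_rows
from .pangenome import classify, curve_rows, development_curve, heap_fit
from .phylo import align_group, concat_and_distance, nj_tree, phylip_lower_triangle, square_tsv_rows
from .secretome import DEFAULT_CUTOFF, pan_secretome, score_panel
from .similarity import ScoringParams, all_vs_all
from .surface_screen import gc_report, presence_rows, screen

log = logging.getLogger("srvpan")


@dataclass
class RunConfig:
    genomes: dict[str, str]                  # genome_id -> proteome FASTA path
    reference: str
    out_dir: str
    nucleotides: dict[str, str] = field(default_factory=dict)
    outgroup_db: str | None = None
    seeds: str | None = None                 # FASTA of surface-screen queries
    operons: dict[str, list[str]] = field(default_factory=dict)
    srv_threshold: float = DEFAULT_SRV_THRESHOLD
    secretion_cutoff: float = DEFAULT_CUTOFF
    evalue_cutoff: float = 1e-4
    n_permutations: int = 100
    rng_seed: int = 0
    distance_correction: str = "poisson"

    def __post_init__(self) -> None:
        if self.reference not in self.genomes:
            raise ValueError(f"reference {self.reference!r} not among configured genomes")
        if not 0 <= self.srv_threshold <= 100:
            raise ValueError("srv_threshold must be in [0, 100]")
        if not 0 <= self.secretion_cutoff <= 1:
            raise ValueError("secretion_cutoff must be in [0, 1]")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def scoring_params(self) -> ScoringParams:
        return ScoringParams(evalue_cutoff=self.evalue_cutoff)


def _read_fasta_pairs(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def run_all(config: RunConfig, panel: list[Genome] | None = None) -> str:
    """Execute the full pipeline; returns the report directory path."""
    out_dir = config.out_dir
    created = not os.path.isdir(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    stage = "setup"
    try:
        params = config.scoring_params()

        if panel is None:
            stage = "io"
            panel = []
            for gid in config.genomes:  # config order defines panel order
                genome = read_proteome(config.genomes[gid], gid)
                if gid in config.nucleotides:
                    attach_nucleotides(genome, config.nucleotides[gid])
                panel.append(genome)
        log.info("io: %d genomes, %d ORFs", len(panel), sum(g.n_orfs for g in panel))

        stage = "similarity"
        table = all_vs_all(panel, params)
        log.info("similarity: %d directed hits", len(table))

        stage = "orthology"
        groups = build_groups(panel, table, config.reference, config.srv_threshold)
        write_table(
            group_table_rows(groups, table),
            ["group_id", "genome_id", "locus_tag", "seeded_by", "srv_to_seed"],
            os.path.join(out_dir, "groups.tsv"),
        )
        log.info("orthology: %d groups", len(groups))

        stage = "pangenome"
        outgroup = _read_fasta_pairs(config.outgroup_db) if config.outgroup_db else None
        cls = classify(panel, groups, outgroup, params)
        write_classification_table(cls.gene_labels, os.path.join(out_dir, "classification.tsv"))
        curve = development_curve(panel, groups, config.n_permutations, config.rng_seed)
        write_table(
            curve_rows(curve), ["N", "ordering", "pan", "core"],
            os.path.join(out_dir, "curve.tsv"),
        )
        fit = heap_fit(curve)
        log.info("pangenome: pan=%d core=%d alpha=%.3f", cls.pan_size, cls.core_size, fit.alpha)

        stage = "secretome"
        calls = score_panel(panel, config.secretion_cutoff)
        sec = pan_secretome(panel, groups, cls, calls, config.secretion_cutoff)
        sec_rows = [
            {"group_id": gid, "compartment": "core" if gid in set(sec.core_secretome) else "dispensable"}
            for gid in sec.secretome_groups
        ]
        write_table(sec_rows, ["group_id", "compartment"], os.path.join(out_dir, "secretome.tsv"))
        log.info("secretome: %d groups (%d core)", sec.size, len(sec.core_secretome))

        stage = "phylo"
        core_groups = [g for g in groups if g.group_id in set(cls.core_groups)]
        aligned = [align_group(g, panel, config.reference, params) for g in core_groups]
        D = concat_and_distance(aligned, config.distance_correction)
        tree = nj_tree(D)
        with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
            fh.write(tree.newick + "\n")
        with open(os.path.join(out_dir, "distances.phylip"), "w") as fh:
            fh.write(phylip_lower_triangle(D))
        write_table(
            square_tsv_rows(D), ["taxon"] + D.taxa, os.path.join(out_dir, "distances.tsv")
        )
        log.info("phylo: %d core groups, %d taxa", len(aligned), len(D.taxa))

        stage = "surface_screen"
        matrix = None
        if config.seeds:
            seeds = _read_fasta_pairs(config.seeds)
            matrix = screen(seeds, panel, config.srv_threshold, config.operons or None, params)
            write_table(
                presence_rows(matrix), ["seed"] + matrix.genomes,
                os.path.join(out_dir, "presence.tsv"),
            )
            matched = sorted(
                locus for row in matrix.cells.values() for locus in row.values() if locus
            )
            reports = gc_report(panel, matched)
            write_table(
                [
                    {
                        "locus_tag": r.locus_tag,
                        "gc_percent": r.gc_percent,
                        "genome_gc_percent": r.genome_gc_percent,
                        "delta": r.delta,
                    }
                    for r in reports
                ],
                ["locus_tag", "gc_percent", "genome_gc_percent", "delta"],
                os.path.join(out_dir, "gc_report.tsv"),
            )
            log.info("surface_screen: %d seeds", len(seeds))

        stage = "report"
        summary = {
            "n_genomes": len(panel),
            "pan": cls.pan_size,
            "core": cls.core_size,
            "dispensable": cls.dispensable_size,
            "unique": cls.unique_size,
            "orfan": len(cls.orfan_loci) if cls.orfan_loci is not None else None,
            "per_genome_unique": cls.per_genome_unique,
            "per_genome_orfan": cls.per_genome_orfan or None,
            "heap": {
                "kappa": round(fit.kappa, 4),
                "gamma": round(fit.gamma, 4),
                "alpha": round(fit.alpha, 4),
                "rss": round(fit.rss, 4),
                "open_pangenome": fit.open_pangenome,
            },
            "secretome": {
                "total": sec.size,
                "core": len(sec.core_secretome),
                "dispensable": len(sec.dispensable_secretome),
                "member_gene_tally": sec.member_gene_tally,
                "per_genome_secreted": sec.per_genome_secreted,
            },
            "operon_calls": matrix.operon_calls if matrix is not None else None,
        }
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

        metadata = {
            "version": __version__,
            "rng_seed": config.rng_seed,
            "parameters": {
                "srv_threshold": config.srv_threshold,
                "secretion_cutoff": config.secretion_cutoff,
                "evalue_cutoff": config.evalue_cutoff,
                "n_permutations": config.n_permutations,
                "distance_correction": config.distance_correction,
                "scoring": asdict(params),
            },
            "decisions": {
                "grouping": "reference-seeded RBBH, no transitive closure",
                "srv_rule": "strictly greater than threshold",
                "orfan_rule": "E-value cutoff only, no SRV",
                "heap_summary": "median pan size over permuted orderings",
                "alignment": "reference-star global alignment",
            },
        }
        with open(os.path.join(out_dir, "run_metadata.json"), "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return out_dir
    except Exception as exc:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
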