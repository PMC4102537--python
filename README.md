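# srvpan

Comparative pan-genome analysis for bacterial strain panels, built around the
score-ratio-value (SRV) flavour of reciprocal-best-hit orthology. The package
re-implements, as a tested and reusable pipeline, the comparative survey
style applied to 13 *Lactobacillus rhamnosus* genomes: pan/core/dispensable/
unique/ORFan partitioning, Heap's-law openness, a classical (Sec-pathway)
pan-secretome, a core-genome neighbor-joining phylogeny, and a
presence/absence screen for surface-protein loci with G+C anomaly reporting.
It ships a ground-truthed synthetic strain-panel generator so every stage is
testable end to end without downloads.

It is written for microbial comparative genomicists who want the whole chain
— similarity search, orthology, partitioning, fitting, tree building — as
inspectable, deterministic library code rather than a lattice of external
binaries.

## The method

**Similarity.** All-vs-all Smith–Waterman under BLOSUM62 with affine gaps
(gap of length *k* costs 11 + *k*), Karlin–Altschul statistics
bit = (λS − ln K)/ln 2, E = m·n·2^(−bit) with λ = 0.267, K = 0.041, and an
E-value cutoff of 1 × 10⁻⁴. A shared-4-mer prescreen keeps panels at desk
scale; it can be disabled.

**Orthology.** Every hit is normalized by the query's self-hit score:
SRV = 100 · S(q, s) / S(q, q) ∈ [0, 100]. Two cross-genome genes are
orthologs when they are reciprocal best hits and SRV > 35 strictly in both
directions. Multi-genome groups are seeded from a designated reference
strain, then remaining genes are swept genome by genome.

**Pan-genome.** Core = groups with a member in every genome; dispensable =
the rest; unique = single-genome groups; ORFan = genes with no E ≤ 10⁻⁴ hit
in an outgroup protein database. Openness comes from Heap's law: median pan
size over permuted genome orderings is fitted to κ·N^γ by nonlinear least
squares, with α = 1 − γ and α < 1 read as an open pan-genome.

**Secretome.** A pluggable signal-peptide scorer (a deterministic tripartite
n/h/c-region heuristic stands in for a trained Gram-positive predictor;
precomputed scores can be substituted) calls secreted proteins at a
cutoff of 0.45; groups enter the secretome by majority vote and inherit
core/dispensable status.

**Phylogeny.** Core groups are star-aligned around the reference member
(Needleman–Wunsch, BLOSUM62, 11/1), columns with gaps or < 50% conservation
are removed, kept columns are concatenated, distances are Poisson-corrected
(−ln(1 − p)), and the tree is Saitou–Nei neighbor joining (exact on additive
matrices), emitted as Newick.

**Surface screen.** Seed query proteins (e.g. pilin operon subunits) are
matched per genome by the same RBBH + SRV rule; operons count as present
only when all subunits are; matched loci get G+C content compared against
the whole-genome background.

## Worked example

Simulate a ground-truthed 6-strain panel and partition it:

```
$ srvpan simulate --seed 5 --strains 6 --genes 30 --out demo/panel
wrote 6 genomes + truth to demo/panel

$ srvpan classify demo/panel/S0*.faa --reference S01 \
    --outgroup demo/panel/outgroup.faa --permutations 50 --seed 5 \
    --out demo/report
{"core": 25, "dispensable": 26, "heap_alpha": 0.7284, "open_pangenome": true,
 "orfan": 25, "pan": 51, "unique": 17}

$ srvpan tree demo/panel/S0*.faa --reference S01 --out demo/tree.nwk
wrote tree over 6 taxa to demo/tree.nwk
$ cat demo/tree.nwk
(S03:0.012764,S06:0.010287,(S01:0.013672,(S04:0.006434,(S02:0.015149,S05:0.005522):0.011415):0.027887):0.005629):0.000000;
```

Reading the numbers: 51 ortholog groups make up the pan-genome, of which 25
are present in all six strains (core) and 26 are accessory; 17 groups are
strain-specific, and 25 genes have no qualifying hit in the outgroup
database (here, the gained genes the simulator planted). α ≈ 0.73 < 1 flags
an open pan-genome — the simulator gains new genes on every terminal branch,
so the pan size keeps growing as strains are added. The Newick tree is the
unrooted core-genome phylogeny; on this panel it matches the generating
topology exactly (`demo/panel/truth_tree.nwk`).

The same stages are available as a single `srvpan run-all config.yaml` (see
`srvpan.pipeline.RunConfig` for the schema) and as library functions.

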