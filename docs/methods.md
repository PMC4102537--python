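# Methods

This note records the models, parameter choices, numerical details and known
limitations of the pipeline, in the order the stages run.

## Similarity statistics

Local alignment is optimal Smith–Waterman under BLOSUM62 with affine gap
costs in the BLAST convention: a gap of length *k* costs
`gap_open + k * gap_extend` with defaults 11/1. The engine is Biopython's
`PairwiseAligner` (C implementation); its scores are verified in the test
suite against an independent hand-written Gotoh dynamic program.

Bit scores and E-values use the Karlin–Altschul closed forms

    bit = (λ·S − ln K) / ln 2,     E = m · n · 2^(−bit)

with the gapped-BLOSUM62 constants λ = 0.267, K = 0.041. Two deliberate
simplifications, both configurable through `ScoringParams`:

* no effective-length ("length adjustment") correction — m and n are raw
  query and database lengths. The E cutoff (1e-4) is permissive by design;
  orthology decisions are driven by the score ratio, not by E.
* a shared-k-mer prescreen (default: ≥ 3 shared 4-mers) skips the full DP
  for pairs that cannot plausibly reach the cutoff. A qualifying hit at
  E ≤ 1e-4 needs a raw score around 66 under these constants, which at any
  realistic identity implies far more than three conserved 4-mers; the
  property suite verifies on its corpus that prescreened results equal the
  exhaustive run. Disable with `prescreen=False` for exact behaviour.

Self-hits are always computed and always retained, and are keyed by locus:
a gene's self-score never comes from an identical-sequence paralog.

## SRV orthology

SRV = 100 · S(query, subject) / S(query, query), clamped to [0, 100]. An
ortholog pair must be a reciprocal best hit with SRV **strictly** greater
than the threshold (default 35) in both directions; best hits break ties by
lower E-value, then lexicographically smaller subject tag, so results are
independent of input order.

Multi-genome groups are reference-seeded: pass 1 creates one group per
reference-strain gene and attaches each other genome's RBBH partner of that
gene; pass 2 sweeps unassigned genes genome by genome in panel order,
seeding new groups and attaching partners among still-unassigned genes. No
transitive closure is applied through non-reference genomes for
reference-seeded groups; a gene that is best hit of several queries joins
only the first group by pass order. The pass-2 rule is this package's own
resolution of how genes orthologous to each other but to no reference gene
should be grouped across three or more genomes; it is recorded in the run
metadata so results from platforms with different closure rules can be
compared knowingly.

## Pan-genome partition and Heap's law

Core groups span every genome; dispensable is the remainder; unique groups
have exactly one member genome; per-genome unique counts are reported
petal-style. ORFan calls compare each gene against an outgroup protein
database using the E-value cutoff only — SRV normalization is defined
against within-panel self-hits and is not applied across databases. With no
outgroup configured, ORFan status is *undefined* (reported as null), never
silently empty.

Development curves accumulate pan (union) and core (intersection) sizes
over permuted genome orderings (default 100 permutations, seeded, recorded).
Pan is non-decreasing and core non-increasing along every single ordering by
construction, and tests assert it.

The Heap's-law fit regresses the **median** pan size at each N (published fits of this kind
show a single curve without stating which ordering summary it is; the median
is robust to the ordering extremes) against κ·N^γ with `scipy.optimize.curve_fit`,
initialized from a log–log linear regression and run to parameter tolerance
1e-10. α = 1 − γ; α < 1 is reported as an open pan-genome. The alternative
"new genes per added genome ∝ N^(−α)" log–log regression is also emitted
(`alt_alpha_new_genes`) for comparison but is not the headline number.
Degenerate inputs: fewer than three N values or non-positive pan sizes are
errors; a constant curve fits γ = 0, α = 1, closed.

## Secretome

The built-in scorer is a deterministic stand-in for a trained Gram-positive
signal-peptide predictor, combining over the first 45 residues: net positive
charge in residues 1–7 (min–max normalized over [0, 3]), the maximal
8-residue mean Kyte–Doolittle hydrophobicity among windows within residues
3–25 (normalized over [2.0, 3.8] — a genuine h-region is strongly
hydrophobic, and typical globular-segment windows fall below 2), and a
small-residue A-X-A cleavage pattern (G/S allowed for A) ending at positions
15–45; weights 0.25/0.5/0.25, secretion call at score ≥ 0.45. Sequences
shorter than 30 residues score 0 without error.

On random background sequence the heuristic has a small but non-zero
false-positive rate (a few percent, driven by charged N-termini plus a
chance cleavage motif); tests that compare heuristic calls against planted
truth use tolerances that account for it, and the exact-partition test
injects ground-truth scores through the plug-in interface
(`calls_from_scores`) instead. Real predictor outputs can be substituted the
same way; the analysis of record is the partition, not the scorer.

A group enters the secretome when a majority of its members are called
secreted, ties counting as secreted — a group should not drop out of the
secretome because a single member's signal peptide is missed or truncated in
one draft genome. Both the group count and the member-gene tally are
reported, since published surveys do not always say which was counted.

## Core-genome phylogeny

Each core group is star-aligned around its reference-strain member with
global Needleman–Wunsch (BLOSUM62, 11/1, end gaps penalized). Member
residues project onto reference coordinates; insertions relative to the
reference get their own columns, gapped everywhere else — so each member's
residues all appear and alignment length ≥ longest member. The star
construction is deterministic and adequate at within-species core-gene
identities (upwards of ~90%); the distance stage accepts externally aligned
groups if a full progressive MSA is preferred.

Column filter (the gap/conservation stand-in for alignment-block cleaning,
whose original parameters are unstated): keep columns with zero gaps and
≥ 50% identical residues. Kept columns are concatenated in ascending
group-id order; distances are p (mismatch fraction) or the default Poisson
correction −ln(1 − p), with p = 1 an error under the correction.

Neighbor joining follows Saitou–Nei with the standard Q-criterion. Numerical
conventions: ties in Q break toward the smallest (i, j) index pair; a
negative branch length is clamped to zero with the deficit moved to the
sister branch (their sum is preserved); the final three lineages are
resolved by the closed form, clamped at zero. NJ is exact on additive
matrices — property-tested over random trees — and the implementation is
cross-checked against an independent NJ in the test suite. Output is an
unrooted tree (trifurcating root node) in Newick.

## Surface-protein screen

Seeds are matched per genome by the same reciprocal rule as orthology: the
seed's best gene in the genome must reciprocally have that seed as its best
seed, with SRV strictly above threshold both ways. Operons are called
present only when every subunit seed matches; some-but-not-all is reported
"partial", never "present". Percent identity within a matched row is the
minimum over pairs, counted on global-alignment columns excluding terminal
gap overhangs, with internal gaps as mismatches — a floor, matching how
"overall identity" is quoted for full-length homolog alignments. G+C content
is 100·(G+C)/(A+C+G+T) with N excluded from both numerator and denominator,
rounded half-up to one decimal; the per-locus delta is taken against the
host genome's pooled ORF G+C.

## Synthetic panels and what they do (and do not) show

The generator emulates the statistical structure of a ~13-strain
within-species panel, scaled to 100 ancestral genes per strain for
desk-scale all-vs-all (the real panel's ~2,900 ORFs per genome behave the
same way, only larger). Defaults: gene lengths uniform on 80–400 aa;
per-branch gene-loss probability 0.02 (so ~60–70% of ancestral genes remain
core across 13 strains, matching the observed core share); Poisson(3) novel
gene gains per terminal branch (strain-specific by construction, hence true
unique genes and true ORFans); per-site substitution probability
`sub_rate × branch length` with sub_rate 0.01 and branch lengths uniform on
0.5–1.5 along a random bifurcating topology; 10% of ancestral genes carry a
planted signal peptide; a 4-gene pilus-like operon with planted signal
peptides is inserted into 4 designated strains at a G+C target of 44% versus
the 47% genome background — the stand-in for a laterally transferred surface
locus.

Substitutions are drawn with probability ∝ exp(0.6 · BLOSUM62 score) so
homologs stay detectable at the stated rates, as within-species core genes
do. Planted signal peptides (MKK + 12 L/I/V + A-X-A, 18 residues) are
protected from substitution — purifying selection on the export signal —
so secretion truth labels stay valid along the tree. The outgroup database
contains 5%-diverged copies of the ancestral genes only, making gained and
operon genes the exact ORFan truth. Nucleotide sequences are back-generated
by codon choice weighted toward the per-gene G+C target.

What passing these tests shows: the pipeline's partitioning, fitting, tree
and screen recover a known truth under realistic within-species divergence,
gain and loss. What it does not show: robustness to fragmented draft
annotations, paralog expansions, codon-level selection, or horizontal
transfer between extant strains — none of which the generator emulates
(operon planting stands in for transfer events).

## Problem sizes and determinism

Default test/acceptance problem sizes: 13 strains × ~100 genes (~1,300
proteins, ~8–9k qualifying directed hits), 50 curve permutations, and a
second 13-strain panel at sub_rate 0.1 for the divergence stress case.
These sizes were chosen so a full run completes in about a minute on one
core while leaving every stage's statistics (core share, unique counts,
secretome fraction) in the regime the method targets. All randomness flows
through explicit seeds (`SimParams.rng_seed`, curve `rng_seed`); identical
config + seed produces byte-identical report directories, which the tests
assert.

## Known limitations

* E-values lack the effective-length correction, so they are conservative
  for short queries; do not compare them numerically to external search
  tools — the SRV stage is the decision maker.
* Reference-star alignment degrades below roughly 60–70% identity; swap in
  an external MSA for deep panels.
* The secretome heuristic is a stand-in: its absolute calls on real
  proteomes are not comparable to a trained predictor, and real scores
  should be supplied through the score-file plug-in for production use.
* Ingested 12-column hit tables carry bit scores only; SRV then normalizes
  bit by self-bit, which differs from raw-score ratios by the additive
  ln K term (small at qualifying scores).
* The headline counts of the real 13-genome survey are recorded as
  reference bookkeeping, not recomputed: they depend on annotation vintage
  and search-tool behaviour that this package intentionally replaces with
  an in-process, reproducible engine.
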