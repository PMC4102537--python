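"""Published figures for the 13-genome *Lactobacillus rhamnosus* survey.

The strain attribute table and headline pan-genome counts reported for the
real 13-genome panel are kept here as reference inputs: reproducing the full
counts requires downloading the original genome projects and matching their
annotation vintage, so the package treats them as documentation-level
bookkeeping and recomputes only the arithmetic that relates them (averages,
conservation sums, ratios). See the real-data recipe in the README.
"""

from __future__ import annotations

# strain, source, status, genome size (Mbp), G+C %, number of ORFs
STRAIN_TABLE = [
    ("LC705", "milk", "complete", 3.03, 46.6, 3033),
    ("ATCC 8530", "human airways", "complete", 2.96, 46.8, 2977),
    ("GG", "human feces", "complete", 3.01, 46.7, 2985),
    ("ATCC 53103", "human feces", "complete", 3.01, 46.7, 2905),
    ("ATCC 21052", "human feces", "draft", 2.87, 46.7, 3063),
    ("HN001", "dairy starter", "draft", 2.91, 46.6, 2864),
    ("LMS2-1", "human gut", "draft", 3.11, 46.5, 3209),
    ("LRHMDP2", "infected dental pulp", "draft", 2.91, 46.6, 2971),
    ("LRHMDP3", "infected dental pulp", "draft", 2.91, 46.6, 2983),
    ("R0011", "cheddar cheese", "draft", 2.90, 46.7, 2782),
    ("E800", "human feces", "draft", 3.03, 46.6, 3107),
    ("PEL5", "human gut biopsy", "draft", 2.99, 46.7, 2922),
    ("PEL6", "human gut biopsy", "draft", 2.88, 46.7, 2899),
]

REFERENCE_STRAIN = "GG"

# headline counts reported for the real panel
PUBLISHED_COUNTS = {
    "core": 2095,
    "dispensable": 2798,
    "pan": 4893,
    "unique": 855,
    "orfan": 519,
    "secretome_core": 103,
    "secretome_dispensable": 127,
    "secretome": 230,
    "heap_alpha": 0.79,
}

# comparator species: (core, pan) gene counts
COMPARATORS = {
    "L. paracasei": (1800, 4200),
    "L. casei": (1715, 5935),
}


def average_orfs() -> float:
    """Mean ORF count across the 13 strains (rounds to 2,977)."""
    return sum(row[5] for row in STRAIN_TABLE) / len(STRAIN_TABLE)


def average_genome_size_mbp() -> float:
    """Mean genome size in Mbp across the 13 strains (rounds to 2.96)."""
    return sum(row[3] for row in STRAIN_TABLE) / len(STRAIN_TABLE)


def pan_conservation_sum() -> int:
    """core + dispensable, which must equal the pan-genome size."""
    return PUBLISHED_COUNTS["core"] + PUBLISHED_COUNTS["dispensable"]


def secretome_conservation_sum() -> int:
    return PUBLISHED_COUNTS["secretome_core"] + PUBLISHED_COUNTS["secretome_dispensable"]


def core_fraction_pct() -> float:
    """Core share of the pan-genome, percent (about 43%)."""
    return 100.0 * PUBLISHED_COUNTS["core"] / PUBLISHED_COUNTS["pan"]


def secretome_fraction_pct() -> float:
    """Secretome share of the pan-genome, percent (about 4.7%)."""
    return 100.0 * PUBLISHED_COUNTS["secretome"] / PUBLISHED_COUNTS["pan"]


def pan_to_average_fold() -> float:
    """Pan-genome size over the average per-genome ORF count (about 1.6)."""
    return PUBLISHED_COUNTS["pan"] / average_orfs()


def comparator_core_fraction_pct(species: str) -> float:
    core, pan = COMPARATORS[species]
    return 100.0 * core / pan
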