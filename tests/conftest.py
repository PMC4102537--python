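from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from srvpan.genome_io import Gene, Genome
from srvpan.orthology import build_groups
from srvpan.pangenome import classify, development_curve, heap_fit
from srvpan.phylo import align_group, concat_and_distance, nj_tree
from srvpan.secretome import pan_secretome, score_panel
from srvpan.similarity import all_vs_all
from srvpan.surface_screen import screen
from srvpan.synthetic_data import AMINO_ACIDS, SimParams, simulate_panel

DEFAULT_SIM_SEED = 1


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        choices = [c for c in AMINO_ACIDS if c != chars[pos]]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


@pytest.fixture(scope="session")
def toy3_panel():
    """Three tiny genomes with known homology structure.

    Family a spans all three genomes, family b spans two, and c/d/e are
    unrelated singletons, so the expected partition is
    {a1,a2,a3}, {b1,b2}, {c1}, {d2}, {e3}.
    """
    rng = np.random.default_rng(42)
    a = random_protein(rng, 60)
    b = random_protein(rng, 70)
    seqs = {
        "a1": a, "a2": mutate(rng, a, 3), "a3": mutate(rng, a, 5),
        "b1": b, "b2": mutate(rng, b, 4),
        "c1": random_protein(rng, 65),
        "d2": random_protein(rng, 62),
        "e3": random_protein(rng, 68),
    }
    layout = {"G1": ["a1", "b1", "c1"], "G2": ["a2", "b2", "d2"], "G3": ["a3", "e3"]}
    return [
        Genome(gid, [Gene(tag, gid, seqs[tag]) for tag in tags])
        for gid, tags in layout.items()
    ]


@pytest.fixture(scope="session")
def sim():
    """The default ground-truthed 13-strain, 100-gene synthetic panel."""
    panel, truth = simulate_panel(SimParams(rng_seed=DEFAULT_SIM_SEED))
    return SimpleNamespace(panel=panel, truth=truth)


@pytest.fixture(scope="session")
def run(sim):
    """Full pipeline executed once on the default panel; shared across tests."""
    panel, truth = sim.panel, sim.truth
    table = all_vs_all(panel)
    groups = build_groups(panel, table, truth.reference)
    cls = classify(panel, groups, truth.outgroup_db)
    curve = development_curve(panel, groups, n_permutations=50, rng_seed=0)
    fit = heap_fit(curve)
    calls = score_panel(panel)
    sec = pan_secretome(panel, groups, cls, calls)
    core_groups = [g for g in groups if g.group_id in set(cls.core_groups)]
    aligned = [align_group(g, panel, truth.reference) for g in core_groups]
    tree = nj_tree(concat_and_distance(aligned))
    operon_members = [sid for sid, _ in truth.seed_proteins]
    matrix = screen(
        truth.seed_proteins, panel, operons={"pilus_operon": operon_members}
    )
    return SimpleNamespace(
        panel=panel, truth=truth, table=table, groups=groups, cls=cls,
        curve=curve, fit=fit, calls=calls, sec=sec, aligned=aligned,
        tree=tree, matrix=matrix,
    )
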