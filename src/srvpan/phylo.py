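"""Core-genome phylogeny: star alignment, column filtering, distances, NJ.

A reference-star alignment (each member globally aligned to the group's
reference member) replaces a full progressive MSA; at the high identities of
within-species core homologs the two agree after the gap/conservation column
filter, and the star construction is fully deterministic. Externally aligned
FASTA can be substituted upstream.

Distances over concatenated kept columns: p (mismatch fraction) or the
Poisson correction -ln(1 - p). Tree reconstruction is Saitou-Nei neighbor
joining with the standard Q-criterion, ties broken by the smallest (i, j)
index pair, and negative branch lengths clamped to zero with the deficit
moved to the sister branch. NJ is exact on additive matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import Genome
from .orthology import OrthologGroup
from .similarity import ScoringParams, _aligner


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_part() for c in self.children)
        return f"({inner}):{self.length:.6f}"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the unrooted tree, each as the smaller-or-
        canonical frozenset of leaf names on one side of an internal edge."""
        all_leaves = frozenset(self.leaves())
        splits: set[frozenset] = set()

        def walk(node: "TreeNode") -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self and 1 < len(below) < len(all_leaves) - 1:
                side = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
                splits.add(side)
            return below

        walk(self)
        return splits


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Symmetric bipartition distance between two unrooted trees."""
    if set(a.leaves()) != set(b.leaves()):
        raise ValueError("trees must share the same leaf set")
    return len(a.bipartitions() ^ b.bipartitions())


@dataclass
class AlignedGroup:
    group_id: str
    rows: dict[str, str]                 # genome_id -> gapped sequence
    kept_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"group {self.group_id}: unequal row lengths")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))


def align_group(
    group: OrthologGroup,
    panel: list[Genome],
    reference: str | None = None,
    params: ScoringParams | None = None,
) -> AlignedGroup:
    """Star alignment of a group around its reference member.

    Each member is globally aligned (Needleman-Wunsch, BLOSUM62, affine 11/1)
    to the member from ``reference`` (falling back to the seeding genome).
    Matched/deleted positions project onto reference coordinates; insertions
    relative to the reference get their own columns (gapped in every other
    row), so the alignment length is at least the longest member.
    """
    if group.size < 2:
        raise ValueError(f"group {group.group_id} has fewer than 2 members")
    params = params or ScoringParams()
    by_id = {g.genome_id: g for g in panel}
    ref_genome = reference if (reference in group.members) else group.seeded_by
    ref_locus = group.members[ref_genome]
    ref_seq = by_id[ref_genome][ref_locus].protein_seq
    aligner = _aligner(params, mode="global")

    others = sorted(gid for gid in group.members if gid != ref_genome)
    L = len(ref_seq)
    # per member: residue (or '-') at each ref position, and insertions keyed
    # by the ref position they precede (L = after the last position)
    projected: dict[str, list[str]] = {}
    insertions: dict[str, dict[int, str]] = {}
    for gid in others:
        seq = by_id[gid][group.members[gid]].protein_seq
        aln = aligner.align(ref_seq, seq)[0]
        ga, gb = str(aln[0]), str(aln[1])
        cols = ["-"] * L
        ins: dict[int, str] = {}
        ref_pos = 0
        for x, y in zip(ga, gb):
            if x == "-":
                ins[ref_pos] = ins.get(ref_pos, "") + (y if y != "-" else "")
            else:
                cols[ref_pos] = y
                ref_pos += 1
        projected[gid] = cols
        insertions[gid] = ins

    row_ids = [ref_genome] + others
    out = {gid: [] for gid in row_ids}
    for pos in range(L + 1):
        for gid in others:
            segment = insertions[gid].get(pos, "")
            for ch in segment:
                for rid in row_ids:
                    out[rid].append(ch if rid == gid else "-")
        if pos < L:
            out[ref_genome].append(ref_seq[pos])
            for gid in others:
                out[gid].append(projected[gid][pos])

    rows = {gid: "".join(chars) for gid, chars in out.items()}
    aligned = AlignedGroup(group_id=group.group_id, rows=rows)
    return filter_columns(aligned)


def filter_columns(aligned: AlignedGroup) -> AlignedGroup:
    """Record columns with zero gaps and >=50% identical residues."""
    n_rows = len(aligned.rows)
    row_values = list(aligned.rows.values())
    kept = []
    for i in range(aligned.length):
        column = [row[i] for row in row_values]
        if "-" in column:
            continue
        if max(column.count(c) for c in set(column)) / n_rows >= 0.5:
            kept.append(i)
    aligned.kept_columns = kept
    return aligned


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix entries must be finite")


def concat_and_distance(
    aligned_groups: list[AlignedGroup],
    correction: str = "poisson",
) -> DistanceMatrix:
    """Concatenate kept columns (ascending group_id) and compute distances."""
    if correction not in ("p", "poisson"):
        raise ValueError("correction must be 'p' or 'poisson'")
    if not aligned_groups:
        raise ValueError("no aligned groups")
    taxa = sorted(aligned_groups[0].rows)
    concat = {t: [] for t in taxa}
    for ag in sorted(aligned_groups, key=lambda a: a.group_id):
        if sorted(ag.rows) != taxa:
            raise ValueError(f"group {ag.group_id} does not cover every genome")
        for t in taxa:
            row = ag.rows[t]
            concat[t].append("".join(row[i] for i in ag.kept_columns))
    seqs = {t: "".join(parts) for t, parts in concat.items()}
    total = len(next(iter(seqs.values())))
    if total == 0:
        raise ValueError("no kept columns across groups")

    n = len(taxa)
    d = np.zeros((n, n))
    arr = {t: np.frombuffer(seqs[t].encode(), dtype="S1") for t in taxa}
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(arr[taxa[i]] != arr[taxa[j]]))
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("p = 1 has no finite Poisson distance")
                dist = -np.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=taxa, d=d)


@dataclass
class StrainTree:
    root: TreeNode

    @property
    def newick(self) -> str:
        return self.root.newick()

    def leaves(self) -> list[str]:
        return sorted(self.root.leaves())


def nj_tree(D: DistanceMatrix) -> StrainTree:
    """Saitou-Nei neighbor joining; exact on additive distance matrices."""
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    d = D.d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj, d[i, j])
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        nodes = [nodes[x] for x in keep] + [new]
        d = d2

    # resolve the final three around a central node (closed form)
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = (max(0.0, x) for x in (la, lb, lc))
    return StrainTree(root=TreeNode(children=[a, b, c]))


def _clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
    if li < 0:
        return 0.0, total
    if lj < 0:
        return total, 0.0
    return li, lj


def phylip_lower_triangle(D: DistanceMatrix) -> str:
    lines = [str(len(D.taxa))]
    for i, t in enumerate(D.taxa):
        vals = " ".join(f"{D.d[i, j]:.6f}" for j in range(i))
        lines.append(f"{t:<12}{vals}".rstrip())
    return "\n".join(lines) + "\n"


def square_tsv_rows(D: DistanceMatrix) -> list[dict]:
    rows = []
    for i, t in enumerate(D.taxa):
        row = {"taxon": t}
        for j, u in enumerate(D.taxa):
            row[u] = f"{D.d[i, j]:.6f}"
        rows.append(row)
    return rows
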