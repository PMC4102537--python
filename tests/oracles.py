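"""Independent brute-force oracles used to pin down expected values.

These are deliberately separate from the package implementation: plain
three-matrix Gotoh dynamic programs (local and global) written directly from
the recurrences, and small enumeration helpers. A gap of length k costs
open + k * extend, matching the package's scoring convention.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal Smith-Waterman score with affine gaps, by explicit DP."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] - (gap_open + gap_extend),
                E[i][j - 1] - gap_extend,
            )
            F[i][j] = max(
                H[i - 1][j] - (gap_open + gap_extend),
                F[i - 1][j] - gap_extend,
            )
            diag = H[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def gotoh_global_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal Needleman-Wunsch score with affine gaps (end gaps penalized)."""
    n, m = len(a), len(b)
    go = gap_open + gap_extend
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -(gap_open + j * gap_extend)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -(gap_open + i * gap_extend)
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]], E[i][j], F[i][j])
    return int(H[n][m])


def enumerate_rbbh(genomes: dict[str, list[str]], scores: dict[tuple[str, str], float],
                   self_scores: dict[str, float], threshold: float = 35.0):
    """Brute-force RBBH pairs between the two genomes of ``genomes``.

    ``scores`` holds symmetric raw scores keyed by ordered (query, subject);
    absent keys mean no hit.
    """
    (ga, genes_a), (gb, genes_b) = genomes.items()
    pairs = set()
    for a in genes_a:
        hits_ab = {b: scores[(a, b)] for b in genes_b if (a, b) in scores}
        if not hits_ab:
            continue
        # tie-break: highest score, then lexicographically smallest subject
        top = max(hits_ab.values())
        best_ab = sorted(b for b, s in hits_ab.items() if s == top)[0]
        hits_ba = {x: scores[(best_ab, x)] for x in genes_a if (best_ab, x) in scores}
        if not hits_ba:
            continue
        top_ba = max(hits_ba.values())
        best_ba = sorted(x for x, s in hits_ba.items() if s == top_ba)[0]
        if best_ba != a:
            continue
        srv_ab = 100.0 * scores[(a, best_ab)] / self_scores[a]
        srv_ba = 100.0 * scores[(best_ab, a)] / self_scores[best_ab]
        if srv_ab > threshold and srv_ba > threshold:
            pairs.add((a, best_ab))
    return pairs


def enumerate_pan_core(membership: dict[str, set[str]]):
    """Pan/core/unique sizes from per-genome group-membership sets."""
    all_groups = set().union(*membership.values())
    core = set.intersection(*membership.values())
    unique = {
        g for g in all_groups
        if sum(1 for s in membership.values() if g in s) == 1
    }
    return len(all_groups), len(core), unique


def enumerate_orderings_pan(membership: dict[str, set[str]]):
    """Pan trajectory for every ordering of the genomes (tiny panels only)."""
    out = {}
    for order in itertools.permutations(membership):
        acc, traj = set(), []
        for g in order:
            acc |= membership[g]
            traj.append(len(acc))
        out[order] = traj
    return out


def tree_path_distances(root) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a TreeNode tree (additive metric)."""
    dists = {}

    def leaf_depths(node):
        if node.is_leaf():
            return {node.name: node.length}
        merged = {}
        below = [leaf_depths(c) for c in node.children]
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for la, da in below[i].items():
                    for lb, db in below[j].items():
                        key = tuple(sorted((la, lb)))
                        dists[key] = da + db
        for sub in below:
            for leaf, depth in sub.items():
                merged[leaf] = depth + node.length
        return merged

    leaf_depths(root)
    return dists
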