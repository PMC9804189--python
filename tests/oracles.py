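"""Independent brute-force oracles used to pin the package implementations.

Everything here is written deliberately naively (explicit loops, exact
arithmetic) and shares no code with the package beyond its public data
types.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np


# ----------------------------------------------------------------------
# pedigree: path-counting inbreeding coefficient
# ----------------------------------------------------------------------

def _paths_up(parents: dict[str, tuple[str | None, str | None]], start: str):
    """All ancestor paths [start, ..., ancestor], including the trivial path."""
    out = [[start]]
    for p in parents.get(start, (None, None)):
        if p is not None:
            for path in _paths_up(parents, p):
                out.append([start] + path)
    return out


def path_counting_inbreeding(parents: dict[str, tuple[str | None, str | None]],
                             individual: str) -> float:
    """Wright's path-counting F: sum over common-ancestor path pairs of
    (1/2)^(n_edges + 1) * (1 + F_ancestor), paths disjoint except at the
    common ancestor."""
    sire, dam = parents.get(individual, (None, None))
    if sire is None or dam is None:
        return 0.0
    total = 0.0
    for p1 in _paths_up(parents, sire):
        for p2 in _paths_up(parents, dam):
            if p1[-1] != p2[-1]:
                continue
            a = p1[-1]
            if set(p1) & set(p2) != {a}:
                continue
            n_edges = (len(p1) - 1) + (len(p2) - 1)
            total += 0.5 ** (n_edges + 1) * (1.0 + path_counting_inbreeding(parents, a))
    return total


# ----------------------------------------------------------------------
# ROH: exhaustive window enumeration
# ----------------------------------------------------------------------

def brute_force_roh(calls: np.ndarray, pos: np.ndarray, window_snp: int,
                    min_snp: int, min_kb: float, max_density_kb_per_snp: float,
                    max_gap_kb: float, hit_threshold: float,
                    max_het: int, max_missing: int) -> list[tuple[int, int, int]]:
    """ROH for one sample on one chromosome: list of (start_bp, end_bp, n_snps).

    Enumerates every window, every SNP's hit rate, every qualifying run,
    with explicit loops.
    """
    m = len(pos)
    if m < window_snp:
        return []
    n_win = m - window_snp + 1
    hom = []
    for w in range(n_win):
        win = calls[w:w + window_snp]
        n_het = sum(1 for g in win if g == 1)
        n_mis = sum(1 for g in win if g == -1)
        hom.append(n_het <= max_het and n_mis <= max_missing)

    qual = []
    for i in range(m):
        starts = [w for w in range(n_win) if w <= i <= w + window_snp - 1]
        hits = sum(1 for w in starts if hom[w])
        qual.append(hits / len(starts) >= hit_threshold)

    segments = []
    run: list[int] = []
    for i in range(m):
        if not qual[i]:
            if run:
                segments.append(run)
                run = []
            continue
        if run and (pos[i] - pos[run[-1]]) > max_gap_kb * 1000:
            segments.append(run)
            run = []
        run.append(i)
    if run:
        segments.append(run)

    out = []
    for run in segments:
        n_snps = len(run)
        length_kb = (pos[run[-1]] - pos[run[0]] + 1) / 1000
        if (n_snps >= min_snp and length_kb >= min_kb
                and length_kb / n_snps <= max_density_kb_per_snp):
            out.append((int(pos[run[0]]), int(pos[run[-1]]), n_snps))
    return out


# ----------------------------------------------------------------------
# HWE: exact enumeration with rational arithmetic
# ----------------------------------------------------------------------

def hwe_brute_force(n_AA: int, n_Aa: int, n_aa: int) -> float:
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_com = n - h - hom_rare
        weights[h] = Fraction(factorial(n) * 2 ** h,
                              factorial(hom_rare) * factorial(h) * factorial(hom_com))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


# ----------------------------------------------------------------------
# random additive trees for NJ
# ----------------------------------------------------------------------

def random_additive_distances(n: int, rng: np.random.Generator):
    """Random additive leaf distance matrix from a random binary tree with
    positive branch lengths, built by agglomerating clusters and summing
    leaf-to-root depths.  Returns (labels, matrix)."""
    labels = [f"L{i}" for i in range(n)]
    clusters = [[i] for i in range(n)]
    depth = [{i: 0.0} for i in range(n)]  # leaf -> distance to cluster root
    D = np.zeros((n, n))
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi, bj = rng.uniform(0.1, 2.0, size=2)
        di = {leaf: d + bi for leaf, d in depth[i].items()}
        dj = {leaf: d + bj for leaf, d in depth[j].items()}
        for la, da in di.items():
            for lb, db in dj.items():
                D[la, lb] = D[lb, la] = da + db
        clusters[i] = clusters[i] + clusters[j]
        depth[i] = {**di, **dj}
        clusters.pop(j)
        depth.pop(j)
    return labels, D
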