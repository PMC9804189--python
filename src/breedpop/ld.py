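"""Linkage-disequilibrium decay from unphased genotypes.

LD between two markers is the squared Pearson correlation (r^2) of their
dosage vectors over samples typed at both markers -- the composite
(genotype) r^2, appropriate for unphased data.  Pairs are formed within
chromosomes up to a maximum distance, and the decay curve averages r^2 in
distance bins with two widths: a fine width up to a break distance and a
coarse width beyond it (the convention of common LD-decay plotting tools).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class LDPair:
    chrom: str
    dist_bp: int
    r2: float


@dataclass
class DecayCurve:
    """Per-bin mean r^2; bins partition (0, max_dist] left-open right-closed."""

    bin_start_bp: np.ndarray
    bin_end_bp: np.ndarray
    mean_r2: np.ndarray   # NaN for empty bins
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_bp": self.bin_start_bp, "bin_end_bp": self.bin_end_bp,
            "mean_r2": self.mean_r2, "n_pairs": self.n_pairs,
        })


def pairwise_r2(gm: GenotypeMatrix, max_dist_kb: float = 2000.0,
                min_samples: int = 4) -> list[LDPair]:
    """All intra-chromosome marker pairs within ``max_dist_kb``.

    Pairs where either marker is monomorphic in the shared complete-case
    subset, or with fewer than ``min_samples`` complete cases, are skipped.
    Small cohorts (n <= 3) are refused: r^2 from so few genotypes is
    meaningless and such breeds are excluded from decay analysis.
    """
    if gm.n_samples <= 3:
        raise ValueError("need more than 3 samples for LD analysis")
    max_dist_bp = max_dist_kb * 1000.0
    pairs: list[LDPair] = []
    chroms = gm.markers.chrom.astype(str)
    pos = gm.markers.pos_bp

    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        if len(idx) < 2:
            continue
        p = pos[idx]
        g = gm.calls[:, idx].astype(float)
        o = gm.calls[:, idx] != MISSING
        m = len(idx)
        for a in range(m - 1):
            hi = np.searchsorted(p, p[a] + max_dist_bp, side="right")
            for b in range(a + 1, hi):
                if p[b] == p[a]:
                    continue
                both = o[:, a] & o[:, b]
                if both.sum() < min_samples:
                    continue
                x, y = g[both, a], g[both, b]
                sx, sy = x.std(), y.std()
                if sx < 1e-12 or sy < 1e-12:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                pairs.append(LDPair(str(c), int(p[b] - p[a]), float(r * r)))
    return pairs


def decay_curve(pairs: list[LDPair], bin1_bp: int = 100, bin2_bp: int = 3000,
                break_bp: int = 2000, max_dist_bp: int | None = None) -> DecayCurve:
    """Two-regime binned mean r^2 by distance.

    Distances in (0, break_bp] are binned at ``bin1_bp`` width and larger
    distances at ``bin2_bp`` width; bins are left-open right-closed.  Empty
    bins are reported with count 0 and NaN mean.
    """
    if bin1_bp <= 0 or bin2_bp <= 0 or break_bp <= 0:
        raise ValueError("bin widths and break must be positive")
    if break_bp % bin1_bp != 0:
        raise ValueError("break must be a multiple of bin1")
    dists = np.array([p.dist_bp for p in pairs], dtype=float)
    r2 = np.array([p.r2 for p in pairs], dtype=float)
    if max_dist_bp is None:
        max_dist_bp = int(dists.max()) if len(dists) else break_bp

    edges = list(range(0, break_bp + 1, bin1_bp))
    e = break_bp
    while e < max_dist_bp:
        e += bin2_bp
        edges.append(e)
    edges_arr = np.array(edges, dtype=float)

    # left-open right-closed: distance d goes to bin i with edges (e_i, e_{i+1}]
    which = np.searchsorted(edges_arr, dists, side="left") - 1
    nb = len(edges_arr) - 1
    counts = np.zeros(nb, dtype=np.int64)
    sums = np.zeros(nb)
    valid = (which >= 0) & (which < nb)
    np.add.at(counts, which[valid], 1)
    np.add.at(sums, which[valid], r2[valid])
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DecayCurve(
        bin_start_bp=edges_arr[:-1].astype(np.int64),
        bin_end_bp=edges_arr[1:].astype(np.int64),
        mean_r2=means,
        n_pairs=counts,
    )


def subsample_individuals(gm: GenotypeMatrix, n: int, seed: int = 0) -> GenotypeMatrix:
    """Seed-deterministic uniform subsample of individuals, no replacement."""
    if n > gm.n_samples:
        raise ValueError(f"cannot sample {n} of {gm.n_samples} individuals")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(gm.n_samples, size=n, replace=False))
    return gm.subset_samples(idx)


def pairs_to_frame(pairs: list[LDPair]) -> pd.DataFrame:
    return pd.DataFrame([{"chrom": p.chrom, "dist_bp": p.dist_bp, "r2": p.r2}
                         for p in pairs], columns=["chrom", "dist_bp", "r2"])
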