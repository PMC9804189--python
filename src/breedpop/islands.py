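"""ROH islands: population-level homozygosity hotspots as selection signals.

For every marker the ROH frequency is the fraction of samples whose called
ROH cover its position.  Markers whose frequency falls in the top percentile
of the empirical distribution (nearest-rank quantile; ties included) are
marked, and maximal runs of consecutive marked markers on a chromosome form
islands.  Island coordinates span the first to the last marked SNP.  Islands
called independently on two datasets (e.g. SNP array and WGS) can be
intersected in bp space, and genes overlapping an island by at least one
base pair can be listed from a BED annotation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MarkerMap
from .roh import ROHSegment


@dataclass
class SNPROHFrequency:
    chrom: np.ndarray
    pos_bp: np.ndarray
    freq: np.ndarray  # fraction of samples in ROH at the marker, in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos_bp": self.pos_bp, "freq": self.freq})


@dataclass(frozen=True)
class Island:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_freq: float


def snp_roh_frequency(segments: list[ROHSegment], markers: MarkerMap,
                      sample_ids: list[str]) -> SNPROHFrequency:
    """Per-marker fraction of samples whose ROH cover the position."""
    known = set(sample_ids)
    for s in segments:
        if s.sample_id not in known:
            raise ValueError(f"segment for unknown sample {s.sample_id!r}")
    n = len(sample_ids)
    counts = np.zeros(len(markers), dtype=np.int64)

    # group marker indices per chromosome for positional lookup
    chrom_idx: dict[str, np.ndarray] = {}
    for c in np.unique(markers.chrom.astype(str)):
        chrom_idx[c] = np.flatnonzero(markers.chrom.astype(str) == c)

    # a sample may have overlapping segments only across chromosomes; within
    # a chromosome calls are disjoint, so counting segment hits is per-sample
    # membership as long as segments do not overlap -- guard with per-sample sets
    per_sample: dict[str, list[ROHSegment]] = {}
    for s in segments:
        per_sample.setdefault(s.sample_id, []).append(s)

    for sid, segs in per_sample.items():
        covered = np.zeros(len(markers), dtype=bool)
        for s in segs:
            idx = chrom_idx.get(str(s.chrom))
            if idx is None:
                continue
            p = markers.pos_bp[idx]
            lo = np.searchsorted(p, s.start_bp, side="left")
            hi = np.searchsorted(p, s.end_bp, side="right")
            covered[idx[lo:hi]] = True
        counts += covered
    freq = counts / float(n) if n else np.zeros(len(markers))
    return SNPROHFrequency(markers.chrom.copy(), markers.pos_bp.copy(), freq)


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile, upper variant: the smallest order
    statistic with at most (1-q) of the values strictly above it, i.e. the
    (floor(q*n) + 1)-th order statistic (capped at n).  For q*n non-integer
    this equals the classic ceil(q*n) rank; at integer q*n the upper rank is
    taken so that "top 1%" marks n/100 values, not everything at the tie."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty values")
    rank = min(n, math.floor(q * n) + 1)
    return float(v[rank - 1])


def call_islands(freqs: SNPROHFrequency, top_fraction: float = 0.01) -> list[Island]:
    """Call ROH islands at the top ``top_fraction`` of the frequency distribution.

    The threshold is the (1 - top_fraction) nearest-rank quantile; markers
    with freq >= threshold (ties included) are marked, and maximal runs of
    consecutive marked markers per chromosome become islands.
    """
    m = len(freqs.freq)
    if m < 100:
        warnings.warn(f"only {m} markers: top-{top_fraction:.0%} threshold is unstable")
    threshold = nearest_rank_quantile(freqs.freq, 1.0 - top_fraction)
    if np.all(freqs.freq == freqs.freq[0]):
        warnings.warn("all ROH frequencies identical; every marker marked")
    marked = freqs.freq >= threshold

    islands: list[Island] = []
    chroms = freqs.chrom.astype(str)
    j = 0
    while j < m:
        if not marked[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and marked[k + 1] and chroms[k + 1] == chroms[j]:
            k += 1
        islands.append(Island(
            chrom=chroms[j],
            start_bp=int(freqs.pos_bp[j]),
            end_bp=int(freqs.pos_bp[k]),
            n_snps=k - j + 1,
            peak_freq=float(np.max(freqs.freq[j:k + 1])),
        ))
        j = k + 1
    return islands


def intersect_islands(a: list[Island], b: list[Island]) -> list[tuple[str, int, int]]:
    """Per-chromosome interval intersection of two island sets, merged."""
    out: list[tuple[str, int, int]] = []
    for ia in a:
        for ib in b:
            if ia.chrom != ib.chrom:
                continue
            lo = max(ia.start_bp, ib.start_bp)
            hi = min(ia.end_bp, ib.end_bp)
            if lo <= hi:
                out.append((ia.chrom, lo, hi))
    # merge overlapping/adjacent results per chromosome
    out.sort(key=lambda t: (t[0], t[1]))
    merged: list[tuple[str, int, int]] = []
    for c, lo, hi in out:
        if merged and merged[-1][0] == c and lo <= merged[-1][2] + 1:
            merged[-1] = (c, merged[-1][1], max(merged[-1][2], hi))
        else:
            merged.append((c, lo, hi))
    return merged


# ----------------------------------------------------------------------
# gene annotation
# ----------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of gene spans (chrom, start, end, name, ...).

    BED is 0-based half-open; coordinates are converted to 1-based inclusive
    on read, matching the marker map convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    genes = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start_bp": df[1].astype(np.int64) + 1,
        "end_bp": df[2].astype(np.int64),
        "name": df[3] if df.shape[1] > 3 else [f"feature{i}" for i in range(len(df))],
    })
    return genes.sort_values(["chrom", "start_bp"], kind="mergesort").reset_index(drop=True)


def genes_in_interval(genes: pd.DataFrame, island: Island) -> list[str]:
    """Genes overlapping the island by >= 1 bp, in positional order."""
    if island.chrom not in set(genes["chrom"].astype(str)):
        warnings.warn(f"chromosome {island.chrom!r} absent from annotation")
        return []
    sub = genes[genes["chrom"].astype(str) == island.chrom]
    hit = sub[(sub["end_bp"] >= island.start_bp) & (sub["start_bp"] <= island.end_bp)]
    return list(hit.sort_values("start_bp")["name"])


def islands_to_bed(islands: list[Island], path: str | Path) -> None:
    """Write islands as BED (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start_bp - 1}\t{isl.end_bp}\t"
                     f"n_snps={isl.n_snps};peak={isl.peak_freq:.4f}\n")
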