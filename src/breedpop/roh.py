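"""Runs of homozygosity: sliding-window detection and genomic inbreeding.

A run of homozygosity (ROH) is a contiguous stretch of homozygous genotypes,
the signature of the two parental haplotypes being identical by descent.
Detection scans each sample and chromosome with windows of ``window_snp``
consecutive SNPs; a window is called homozygous when it contains at most
``max_het_per_window`` heterozygous and ``max_missing_per_window`` missing
calls.  Each SNP's hit rate is the fraction of windows containing it that
were called homozygous; SNPs at or above ``hit_threshold`` qualify, maximal
runs of qualifying SNPs are split at inter-SNP gaps larger than
``max_gap_kb``, and runs failing the minimum-SNP, minimum-length, or SNP
density criteria are discarded.

Two named presets mirror common practice: ``ARRAY`` for ~170K SNP-array
density (minimum segment 1 Mb, <= 1 het per window) and ``WGS`` for
sequencing density (minimum 500 kb, <= 5 hets per window, tolerating the
higher raw het error rate of sequence calls).

F_ROH is the summed ROH length divided by the autosomal genome length
(2200 Mb for the dog); F_HOM is the excess-homozygosity coefficient
computed from observed vs expected homozygous genotype counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

DOG_AUTOSOME_MB = 2200.0


@dataclass(frozen=True)
class ROHParams:
    window_snp: int = 50
    min_snp: int = 50
    min_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    hit_threshold: float = 0.05
    max_het_per_window: int = 1
    max_missing_per_window: int = 5

    def __post_init__(self) -> None:
        if self.window_snp < 2:
            raise ValueError("window_snp must be >= 2")
        if not 0.0 < self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must be in (0, 1]")


#: SNP-array preset: minimum segment 1 Mb, 50 kb/SNP density, <=1 het/window.
ARRAY = ROHParams()
#: Whole-genome-sequence preset: minimum 500 kb, 30 kb/SNP, <=5 het/window.
WGS = ROHParams(min_kb=500.0, max_density_kb_per_snp=30.0,
                max_het_per_window=5, max_missing_per_window=3)

PRESETS = {"array": ARRAY, "wgs": WGS}


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start after end")

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0

    @property
    def length_mb(self) -> float:
        return self.length_kb / 1000.0


def _qualifying_snps(het: np.ndarray, miss: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean per-SNP qualification for one sample on one chromosome."""
    m = het.size
    w = params.window_snp
    if m < w:
        return np.zeros(m, dtype=bool)
    kernel = np.ones(w)
    het_counts = np.convolve(het.astype(float), kernel, mode="valid")
    miss_counts = np.convolve(miss.astype(float), kernel, mode="valid")
    hom_win = (het_counts <= params.max_het_per_window + 0.5) & \
              (miss_counts <= params.max_missing_per_window + 0.5)
    n_win = m - w + 1
    prefix = np.concatenate([[0], np.cumsum(hom_win)])
    i = np.arange(m)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    total = (hi - lo + 1).astype(float)
    hits = prefix[hi + 1] - prefix[lo]
    return hits / total >= params.hit_threshold


def detect_roh(gm: GenotypeMatrix, params: ROHParams = ARRAY) -> list[ROHSegment]:
    """Call ROH segments for every sample; see module docstring for the rules."""
    segments: list[ROHSegment] = []
    chroms = gm.markers.chrom
    pos = gm.markers.pos_bp
    max_gap_bp = params.max_gap_kb * 1000.0

    # contiguous blocks per chromosome (map is sorted)
    block_bounds: list[tuple[str, int, int]] = []
    start = 0
    for j in range(1, len(pos) + 1):
        if j == len(pos) or chroms[j] != chroms[start]:
            block_bounds.append((str(chroms[start]), start, j))
            start = j

    warned = set()
    for chrom, a, b in block_bounds:
        if b - a < params.window_snp and chrom not in warned:
            warnings.warn(
                f"chromosome {chrom}: fewer than {params.window_snp} markers, no ROH called"
            )
            warned.add(chrom)

    for i, sid in enumerate(gm.sample_ids):
        row = gm.calls[i]
        for chrom, a, b in block_bounds:
            calls = row[a:b]
            p = pos[a:b]
            qual = _qualifying_snps(calls == 1, calls == MISSING, params)
            segments.extend(_runs_to_segments(sid, chrom, p, qual, params, max_gap_bp))
    return segments


def _runs_to_segments(sid, chrom, pos, qual, params, max_gap_bp):
    out = []
    m = len(pos)
    j = 0
    while j < m:
        if not qual[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and qual[k + 1] and (pos[k + 1] - pos[k]) <= max_gap_bp:
            k += 1
        n_snps = k - j + 1
        length_kb = (pos[k] - pos[j] + 1) / 1000.0
        if (n_snps >= params.min_snp and length_kb >= params.min_kb
                and length_kb / n_snps <= params.max_density_kb_per_snp):
            out.append(ROHSegment(sid, chrom, int(pos[j]), int(pos[k]), n_snps))
        j = k + 1
    return out


# ----------------------------------------------------------------------
# inbreeding coefficients
# ----------------------------------------------------------------------

def f_roh(segments: list[ROHSegment], autosome_length_mb: float = DOG_AUTOSOME_MB) -> float:
    """Fraction of the autosomal genome in ROH for one sample's segments."""
    sids = {s.sample_id for s in segments}
    if len(sids) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(sids)}")
    total_mb = sum(s.length_mb for s in segments)
    if total_mb < 0:
        raise ValueError("negative total segment length")
    return total_mb / autosome_length_mb


def f_roh_per_sample(segments: list[ROHSegment], sample_ids: list[str],
                     autosome_length_mb: float = DOG_AUTOSOME_MB) -> pd.Series:
    """F_ROH for every sample (zero for samples without segments)."""
    total = {sid: 0.0 for sid in sample_ids}
    for s in segments:
        if s.sample_id not in total:
            raise ValueError(f"segment for unknown sample {s.sample_id!r}")
        total[s.sample_id] += s.length_mb
    return pd.Series({sid: t / autosome_length_mb for sid, t in total.items()},
                     name="f_roh")


def f_hom(gm: GenotypeMatrix) -> pd.Series:
    """Excess-homozygosity inbreeding coefficient per sample.

    F = (O_hom - E_hom) / (L - E_hom), where O_hom counts the sample's
    homozygous calls, L its non-missing markers, and E_hom the expected
    homozygous count under Hardy-Weinberg using sample-wide allele
    frequencies with the small-sample correction T/(T-1) (T = non-missing
    allele count at the marker).  Markers with T < 2 are skipped.
    """
    obs = gm.calls != MISSING
    T = 2.0 * obs.sum(axis=0)
    usable = T >= 2
    p = gm.allele_b_frequency()
    exp_hom_j = np.zeros(gm.n_markers)
    exp_hom_j[usable] = 1.0 - 2.0 * p[usable] * (1.0 - p[usable]) * T[usable] / (T[usable] - 1.0)

    use = obs & usable
    L = use.sum(axis=1).astype(float)
    o_hom = (use & (gm.calls != 1)).sum(axis=1).astype(float)
    e_hom = use @ exp_hom_j
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / (L - e_hom)
    return pd.Series(f, index=gm.sample_ids, name="f_hom")


def roh_length_classes(segments: list[ROHSegment], breaks_mb: list[float]) -> pd.DataFrame:
    """Count segments per length class per sample.

    ``breaks_mb`` are ascending internal cutoffs; classes are half-open
    [b_i, b_{i+1}) with an initial [0, b_1) and a final [b_k, inf) class.
    """
    if list(breaks_mb) != sorted(breaks_mb):
        raise ValueError("breaks must be ascending")
    edges = [0.0, *breaks_mb, np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f">={lo:g}Mb" if np.isinf(hi) else f"[{lo:g},{hi:g})Mb")
    samples = sorted({s.sample_id for s in segments})
    counts = pd.DataFrame(0, index=samples, columns=labels, dtype=int)
    for s in segments:
        cls = int(np.searchsorted(np.asarray(breaks_mb), s.length_mb, side="right"))
        counts.loc[s.sample_id, labels[cls]] += 1
    return counts


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample": s.sample_id, "chrom": s.chrom, "start_bp": s.start_bp,
          "end_bp": s.end_bp, "n_snps": s.n_snps, "length_kb": s.length_kb}
         for s in segments],
        columns=["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"],
    )


def frame_to_segments(df: pd.DataFrame) -> list[ROHSegment]:
    return [ROHSegment(r.sample, str(r.chrom), int(r.start_bp), int(r.end_bp), int(r.n_snps))
            for r in df.itertuples(index=False)]
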