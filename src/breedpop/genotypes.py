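"""Biallelic SNP genotype panels: PLINK text I/O, merging, and quality control.

Genotypes live in a :class:`GenotypeMatrix`: samples x markers, each call in
{0, 1, 2} counting copies of allele_b (the minor allele at load time), with
-1 for missing.  Marker coordinates are 1-based (chromosome, bp), sorted and
unique, as in a PLINK MAP file.

Panels genotyped on different arrays are merged on exact genomic location
(chromosome + position); allele labels are reconciled by dosage flip and/or
strand complement, and strand-ambiguous A/T and C/G markers are dropped.
QC applies the conventional thresholds (sample call rate, marker call rate,
minor allele frequency, Hardy-Weinberg exact test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MarkerMap:
    """Marker coordinates and allele labels, sorted by (chrom, pos_bp)."""

    chrom: np.ndarray   # str array
    pos_bp: np.ndarray  # int array, 1-based
    name: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.name = np.asarray(self.name, dtype=object)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        n = len(self.pos_bp)
        if not all(len(a) == n for a in (self.chrom, self.name, self.allele_a, self.allele_b)):
            raise ValueError("marker map arrays have inconsistent lengths")
        keys = list(zip(self.chrom, self.pos_bp))
        if keys != sorted(keys, key=lambda t: (_chrom_sort_key(t[0]), t[1])):
            raise ValueError("marker map not sorted by (chrom, pos)")
        if len(set(keys)) != n:
            raise ValueError("duplicate (chrom, pos) in marker map")

    def __len__(self) -> int:
        return len(self.pos_bp)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chrom[idx], self.pos_bp[idx], self.name[idx],
                         self.allele_a[idx], self.allele_b[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos_bp": self.pos_bp, "name": self.name,
            "allele_a": self.allele_a, "allele_b": self.allele_b,
        })


def _chrom_sort_key(c: str):
    return (0, int(c), "") if str(c).isdigit() else (1, 0, str(c))


@dataclass
class GenotypeMatrix:
    """n samples x m markers; calls count copies of allele_b; -1 = missing."""

    sample_ids: list[str]
    markers: MarkerMap
    calls: np.ndarray  # int8, shape (n, m)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError("calls shape inconsistent with samples/markers")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype calls outside {0,1,2,missing}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_b_frequency(self) -> np.ndarray:
        """Per-marker frequency of allele_b among non-missing calls (NaN if
        no calls)."""
        obs = self.calls != MISSING
        dose = np.where(obs, self.calls, 0).sum(axis=0).astype(float)
        n2 = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n2 > 0, dose / n2, np.nan)

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix([self.sample_ids[i] for i in idx],
                              self.markers, self.calls[idx])

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(list(self.sample_ids), self.markers.subset(idx),
                              self.calls[:, idx])


# ----------------------------------------------------------------------
# PLINK text I/O
# ----------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a GenotypeMatrix.

    Allele pairs are recoded to 0/1/2 copies of the dataset-wide minor
    allele per marker; "0 0" is missing.  Triallelic markers or alleles
    outside {A,C,G,T,0} are an error naming the marker.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "name", "cm", "pos"], dtype=str)
    m = len(mp)
    chroms = mp["chrom"].to_numpy(dtype=object)
    names = mp["name"].to_numpy(dtype=object)
    pos = mp["pos"].astype(np.int64).to_numpy()

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"PED line {ln}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            alleles = np.array(fields[6:], dtype=object)
            allele_rows.append(alleles)
    a1 = np.array([row[0::2] for row in allele_rows], dtype=object)
    a2 = np.array([row[1::2] for row in allele_rows], dtype=object)

    n = len(sample_ids)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    al_a = np.empty(m, dtype=object)
    al_b = np.empty(m, dtype=object)
    for j in range(m):
        col = np.concatenate([a1[:, j], a2[:, j]])
        bad = set(col) - set("ACGT0")
        if bad:
            raise ValueError(f"marker {names[j]}: invalid alleles {sorted(bad)}")
        observed = [a for a in col if a != "0"]
        uniq = sorted(set(observed))
        if len(uniq) > 2:
            raise ValueError(f"marker {names[j]}: more than two alleles {uniq}")
        counts = {u: observed.count(u) for u in uniq}
        if len(uniq) == 0:
            major, minor = "0", "0"
        elif len(uniq) == 1:
            major, minor = uniq[0], "0"
        else:
            # minor = less frequent; tie broken alphabetically for determinism
            uniq.sort(key=lambda u: (counts[u], u))
            minor, major = uniq[0], uniq[1]
        al_a[j], al_b[j] = major, minor
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        dose = (a1[:, j] == minor).astype(np.int8) + (a2[:, j] == minor).astype(np.int8)
        calls[:, j] = np.where(miss, MISSING, dose)

    order = sorted(range(m), key=lambda j: (_chrom_sort_key(chroms[j]), pos[j]))
    order = np.array(order)
    markers = MarkerMap(chroms[order], pos[order], names[order], al_a[order], al_b[order])
    return GenotypeMatrix(sample_ids, markers, calls[:, order])


def write_plink_text(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PLINK text PED/MAP (family id = sample id, parents/sex/pheno 0)."""
    mk = gm.markers
    with open(map_path, "w") as fh:
        for j in range(len(mk)):
            fh.write(f"{mk.chrom[j]}\t{mk.name[j]}\t0\t{mk.pos_bp[j]}\n")
    a = np.where(mk.allele_a == "0", "A", mk.allele_a)
    b = np.where(mk.allele_b == "0", "C", mk.allele_b)
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            row = gm.calls[i]
            pairs = []
            for j in range(len(mk)):
                g = row[j]
                if g == MISSING:
                    pairs.append("0 0")
                elif g == 0:
                    pairs.append(f"{a[j]} {a[j]}")
                elif g == 1:
                    pairs.append(f"{a[j]} {b[j]}")
                else:
                    pairs.append(f"{b[j]} {b[j]}")
            fh.write(f"{sid} {sid} 0 0 0 0 " + " ".join(pairs) + "\n")


# ----------------------------------------------------------------------
# merging
# ----------------------------------------------------------------------

@dataclass
class MergeReport:
    n_common_markers: int = 0
    n_flipped: list[int] = field(default_factory=list)       # dosage flips per panel
    n_strand_fixed: list[int] = field(default_factory=list)  # complement recodes per panel
    n_palindromic_dropped: int = 0
    n_incompatible_dropped: int = 0


def merge_panels(panels: list[GenotypeMatrix]) -> tuple[GenotypeMatrix, MergeReport]:
    """Merge >= 2 panels on exact (chromosome, position).

    The merged marker set is the intersection of locations.  Allele labels
    are reconciled against the first panel: a swapped pair flips dosages
    (g -> 2 - g); an opposite-strand pair is complemented (with a flip if
    also swapped); strand-ambiguous A/T and C/G markers and label-
    incompatible markers are dropped and counted.  Samples are concatenated;
    duplicate sample ids across panels are an error.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to merge")
    seen: set[str] = set()
    for p in panels:
        for sid in p.sample_ids:
            if sid in seen:
                raise ValueError(f"duplicate sample id across panels: {sid!r}")
            seen.add(sid)

    keysets = []
    for p in panels:
        keysets.append({(c, int(x)): j
                        for j, (c, x) in enumerate(zip(p.markers.chrom, p.markers.pos_bp))})
    common = set(keysets[0])
    for ks in keysets[1:]:
        common &= set(ks)
    report = MergeReport(n_flipped=[0] * len(panels), n_strand_fixed=[0] * len(panels))
    if not common:
        warnings.warn("no common marker positions across panels")
    common_sorted = sorted(common, key=lambda t: (_chrom_sort_key(t[0]), t[1]))

    ref = panels[0]
    keep_keys = []
    per_panel_cols: list[list[int]] = [[] for _ in panels]
    per_panel_flip: list[list[bool]] = [[] for _ in panels]
    for key in common_sorted:
        j0 = keysets[0][key]
        a_ref, b_ref = ref.markers.allele_a[j0], ref.markers.allele_b[j0]
        if _is_palindromic(a_ref, b_ref):
            report.n_palindromic_dropped += 1
            continue
        cols, flips, ok = [j0], [False], True
        for pi in range(1, len(panels)):
            j = keysets[pi][key]
            mk = panels[pi].markers
            res = _reconcile(a_ref, b_ref, mk.allele_a[j], mk.allele_b[j])
            if res is None:
                ok = False
                break
            flip, strand = res
            cols.append(j)
            flips.append(flip)
            if flip:
                report.n_flipped[pi] += 1
            if strand:
                report.n_strand_fixed[pi] += 1
        if not ok:
            report.n_incompatible_dropped += 1
            continue
        keep_keys.append(key)
        for pi in range(len(panels)):
            per_panel_cols[pi].append(cols[pi])
            per_panel_flip[pi].append(flips[pi])

    report.n_common_markers = len(keep_keys)
    j_ref = np.array(per_panel_cols[0], dtype=int)
    markers = ref.markers.subset(j_ref)

    blocks = []
    for pi, p in enumerate(panels):
        cols = np.array(per_panel_cols[pi], dtype=int)
        sub = p.calls[:, cols].copy()
        flip = np.array(per_panel_flip[pi], dtype=bool)
        if flip.any():
            block = sub[:, flip]
            obs = block != MISSING
            sub[:, flip] = np.where(obs, 2 - block, MISSING)
        blocks.append(sub)
    calls = np.vstack(blocks) if blocks else np.empty((0, 0), dtype=np.int8)
    sample_ids = [sid for p in panels for sid in p.sample_ids]
    return GenotypeMatrix(sample_ids, markers, calls), report


def _is_palindromic(a: str, b: str) -> bool:
    return a in _COMPLEMENT and _COMPLEMENT[a] == b


def _reconcile(a_ref: str, b_ref: str, a: str, b: str) -> tuple[bool, bool] | None:
    """Return (flip_dosage, strand_fixed) mapping (a, b) onto (a_ref, b_ref),
    or None if the labels are incompatible.  '0' (monomorphic placeholder)
    matches anything without flipping."""
    def match(x, y):
        return x == y or x == "0" or y == "0"
    if match(a, a_ref) and match(b, b_ref):
        return False, False
    if match(a, b_ref) and match(b, a_ref):
        return True, False
    ca = _COMPLEMENT.get(a, None)
    cb = _COMPLEMENT.get(b, None)
    if ca is not None or cb is not None:
        ca = ca if a != "0" else "0"
        cb = cb if b != "0" else "0"
        if ca is not None and cb is not None:
            if match(ca, a_ref) and match(cb, b_ref):
                return False, True
            if match(ca, b_ref) and match(cb, a_ref):
                return True, True
    return None


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditional on the sample size n and minor-allele count n_A, the
    heterozygote count has probability proportional to
    n! / (n_AA! n_Aa! n_aa!) * 2**n_Aa.  The two-sided p-value sums the
    probabilities of all outcomes no more probable than the observed one
    (Wigginton-style exact test, no mid-p correction).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_AA + n_Aa  # copies of the allele counted by n_AA
    rare = min(n_a, 2 * n - n_a)
    # enumerate all heterozygote counts with the same parity as `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        n_hom_rare = (rare - h) // 2
        n_hom_com = n - h - n_hom_rare
        return (gammaln(n + 1) - gammaln(n_hom_rare + 1) - gammaln(h + 1)
                - gammaln(n_hom_com + 1) + h * np.log(2.0))

    lp = logprob(hets)
    lp -= np.max(lp)
    p = np.exp(lp)
    p /= p.sum()
    obs = p[hets == n_Aa][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------

@dataclass
class QCParams:
    maf_min: float = 0.05
    marker_missing_max: float = 0.05
    sample_missing_max: float = 0.05
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("maf_min", "marker_missing_max", "sample_missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    removed_samples: list[str] = field(default_factory=list)
    removed_markers_missing: list[str] = field(default_factory=list)
    removed_markers_maf: list[str] = field(default_factory=list)
    removed_markers_hwe: list[str] = field(default_factory=list)


def qc_filter(gm: GenotypeMatrix, params: QCParams | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply standard QC in a fixed order and report per-stage removals.

    1. drop samples with missing rate > sample_missing_max;
    2. drop markers with missing rate > marker_missing_max (recomputed on
       retained samples);
    3. drop markers with minor allele frequency < maf_min;
    4. drop markers with HWE exact p < hwe_p_min.
    Raises if every sample or every marker would be removed.
    """
    if params is None:
        params = QCParams()
    report = QCReport()

    miss = gm.calls == MISSING
    sample_rate = miss.mean(axis=1) if gm.n_markers else np.zeros(gm.n_samples)
    keep_s = sample_rate <= params.sample_missing_max
    report.removed_samples = [s for s, k in zip(gm.sample_ids, keep_s) if not k]
    if not keep_s.any():
        raise ValueError("QC removed every sample")
    gm = gm.subset_samples(np.flatnonzero(keep_s))

    miss = gm.calls == MISSING
    marker_rate = miss.mean(axis=0)
    keep = marker_rate <= params.marker_missing_max
    report.removed_markers_missing = list(gm.markers.name[~keep])
    gm = gm.subset_markers(np.flatnonzero(keep))

    freq = gm.allele_b_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    keep = ~np.isnan(maf) & (maf >= params.maf_min)
    report.removed_markers_maf = list(gm.markers.name[~keep])
    gm = gm.subset_markers(np.flatnonzero(keep))

    keep = np.ones(gm.n_markers, dtype=bool)
    for j in range(gm.n_markers):
        col = gm.calls[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            continue
        n_bb = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        if hwe_exact_test(n_bb, n_ab, n_aa) < params.hwe_p_min:
            keep[j] = False
    report.removed_markers_hwe = list(gm.markers.name[~keep])
    gm = gm.subset_markers(np.flatnonzero(keep))

    if gm.n_markers == 0:
        raise ValueError("QC removed every marker")
    return gm, report
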