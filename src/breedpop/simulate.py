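"""Synthetic data with known ground truth for every pipeline stage.

Four generators cover the analyses in this package:

* :func:`simulate_pedigree` grows a closed breed over discrete yearly
  cohorts with popular-sire mating (a few males siring a large share of
  each cohort) and Poisson litters -- the demographic regime of pedigree
  dog breeds (mean litter size defaults to 6.1 pups).
* :func:`gene_drop` transmits founder haplotypes down a pedigree with
  Haldane (no-interference) recombination at 1 cM/Mb, tracking founder-
  haplotype labels exactly, so every autozygous (IBD) segment and each
  individual's true inbreeding fraction are known in closed form.
* :func:`simulate_structured` draws admixed genotypes under the
  Balding-Nichols model with known ancestry proportions Q and ancestral
  frequencies P.
* :func:`simulate_ld_haplotypes` builds haplotypes whose inter-marker
  allele correlation decays as exp(-d / decay_bp), a tunable LD decay
  length; :func:`implant_island` overwrites a region with one fixed
  homozygous haplotype in all samples, creating a true ROH island.

The default genome is dog-like: 38 autosomes totalling 2200 Mb.  All
generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, MarkerMap
from .pedigree import FEMALE, MALE, Pedigree, PedigreeRecord

DOG_N_AUTOSOMES = 38
DOG_GENOME_BP = 2_200_000_000


# ----------------------------------------------------------------------
# marker maps
# ----------------------------------------------------------------------

def make_marker_map(n_markers: int, n_chrom: int = DOG_N_AUTOSOMES,
                    genome_bp: int = DOG_GENOME_BP, seed: int = 0) -> MarkerMap:
    """Evenly sized chromosomes with uniformly scattered, sorted markers."""
    rng = np.random.default_rng(seed)
    chrom_len = genome_bp // n_chrom
    per = np.full(n_chrom, n_markers // n_chrom, dtype=int)
    per[: n_markers % n_chrom] += 1
    chroms, pos, names = [], [], []
    for c in range(n_chrom):
        # rejection-sample distinct positions (collisions are rare at any
        # realistic density, so one or two extra rounds suffice)
        draw = np.unique(rng.integers(1, chrom_len + 1, size=per[c]))
        while draw.size < per[c]:
            extra = rng.integers(1, chrom_len + 1, size=per[c] - draw.size + 8)
            draw = np.unique(np.concatenate([draw, extra]))
        p = np.sort(rng.permutation(draw)[: per[c]])
        chroms.extend([str(c + 1)] * per[c])
        pos.extend(p.tolist())
        names.extend([f"snp{c + 1}_{i}" for i in range(per[c])])
    m = len(pos)
    return MarkerMap(np.array(chroms, dtype=object), np.array(pos, dtype=np.int64),
                     np.array(names, dtype=object),
                     np.array(["A"] * m, dtype=object), np.array(["C"] * m, dtype=object))


def chromosome_lengths(markers: MarkerMap, genome_bp: int | None = None) -> dict[str, int]:
    """Chromosome lengths implied by a marker map (equal split of genome_bp
    when given, else the last marker position per chromosome)."""
    chroms = [str(c) for c in dict.fromkeys(markers.chrom.astype(str))]
    if genome_bp is not None:
        L = genome_bp // len(chroms)
        return {c: L for c in chroms}
    out = {}
    for c in chroms:
        out[c] = int(markers.pos_bp[markers.chrom.astype(str) == c].max())
    return out


# ----------------------------------------------------------------------
# configuration and truth
# ----------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-condition parameters for pedigree simulation and gene dropping.

    ``popular_sire_concentration`` is the Gamma shape of per-male breeding
    weights: values << 1 concentrate matings on a few popular sires,
    large values make sire usage uniform.
    """

    seed: int = 0
    n_founders: int = 30
    n_years: int = 10
    mean_litter_size: float = 6.1
    popular_sire_concentration: float = 0.3
    whelp_prob: float = 0.45
    breeding_age: tuple[int, int] = (2, 8)
    countries: tuple[str, ...] = ("NL", "DE")
    markers: MarkerMap | None = None
    genome_bp: int = DOG_GENOME_BP
    cm_per_mb: float = 1.0
    founder_freq_range: tuple[float, float] = (0.05, 0.95)


@dataclass
class TruthSet:
    """Ground truth recorded by the generators."""

    ibd_segments: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    true_f: dict[str, float] = field(default_factory=dict)
    Q: np.ndarray | None = None
    P: np.ndarray | None = None
    islands: list[tuple[str, int, int]] = field(default_factory=list)

    def true_f_min_length(self, sample_id: str, min_bp: int, genome_bp: int) -> float:
        """True autozygosity counting only IBD segments >= min_bp."""
        segs = self.ibd_segments.get(sample_id, [])
        tot = sum(e - s + 1 for _, s, e in segs if e - s + 1 >= min_bp)
        return tot / genome_bp


# ----------------------------------------------------------------------
# pedigree simulation
# ----------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Grow a closed population over yearly cohorts with popular-sire mating.

    Founders appear in year 0; each later year every breeding-age female
    whelps one litter with probability ``whelp_prob``, sired by a male drawn
    with probability proportional to his (Gamma-distributed) weight.  The
    returned pedigree is acyclic and internally consistent, so cleaning it
    changes nothing.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[PedigreeRecord] = []
    males: list[tuple[str, int, float]] = []    # id, birth year, weight
    females: list[tuple[str, int, str]] = []    # id, birth year, country
    counter = 0
    base_year = 2000

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"D{counter:06d}"

    for _ in range(cfg.n_founders):
        id_ = new_id()
        male = rng.random() < 0.5
        country = str(rng.choice(list(cfg.countries)))
        records.append(PedigreeRecord(
            id=id_, sex=MALE if male else FEMALE, birth_year=base_year,
            birth_date=_dt.date(base_year, 1 + int(rng.integers(12)), 1 + int(rng.integers(28))),
            country=country))
        if male:
            males.append((id_, base_year, float(rng.gamma(cfg.popular_sire_concentration) + 1e-9)))
        else:
            females.append((id_, base_year, country))

    lo_age, hi_age = cfg.breeding_age
    for y in range(base_year + 1, base_year + cfg.n_years + 1):
        sires = [(i, w) for i, by, w in males if lo_age <= y - by <= hi_age]
        dams = [(i, c) for i, by, c in females if lo_age <= y - by <= hi_age]
        if not sires or not dams:
            if y - base_year <= hi_age:
                continue  # founders not yet of age is impossible; cohort gap
            raise RuntimeError(
                "population extinct: no breeding pairs left; "
                "increase n_founders or whelp_prob")
        weights = np.array([w for _, w in sires])
        weights = weights / weights.sum()
        for dam_id, dam_country in dams:
            if rng.random() >= cfg.whelp_prob:
                continue
            litter = int(rng.poisson(cfg.mean_litter_size))
            if litter == 0:
                continue
            sire_id = sires[int(rng.choice(len(sires), p=weights))][0]
            date = _dt.date(y, 1 + int(rng.integers(12)), 1 + int(rng.integers(28)))
            for _ in range(litter):
                id_ = new_id()
                male = rng.random() < 0.5
                records.append(PedigreeRecord(
                    id=id_, sire_id=sire_id, dam_id=dam_id,
                    sex=MALE if male else FEMALE, birth_year=y, birth_date=date,
                    country=dam_country))
                if male:
                    males.append((id_, y, float(rng.gamma(cfg.popular_sire_concentration) + 1e-9)))
                else:
                    females.append((id_, y, dam_country))
    return Pedigree(records)


# ----------------------------------------------------------------------
# gene dropping
# ----------------------------------------------------------------------

class _Track:
    """Piecewise-constant founder-haplotype labels along one chromosome.

    ``ends`` are ascending segment end positions (bp, last == chrom length);
    segment i covers (ends[i-1], ends[i]].
    """

    __slots__ = ("ends", "labels")

    def __init__(self, ends: np.ndarray, labels: np.ndarray):
        self.ends = ends
        self.labels = labels

    @classmethod
    def uniform(cls, length: int, label: int) -> "_Track":
        return cls(np.array([length], dtype=np.int64), np.array([label], dtype=np.int64))

    def label_at(self, pos: np.ndarray) -> np.ndarray:
        return self.labels[np.searchsorted(self.ends, pos, side="left")]


def _recombine(t1: _Track, t2: _Track, length: int, morgans: float,
               rng: np.random.Generator) -> _Track:
    """One meiosis: Haldane crossovers (Poisson count, uniform positions)."""
    n_xo = rng.poisson(morgans)
    cur = int(rng.integers(2))
    if n_xo == 0:
        src = (t1, t2)[cur]
        return _Track(src.ends.copy(), src.labels.copy())
    cuts = np.sort(rng.integers(1, length, size=n_xo))
    tracks = (t1, t2)
    ends: list[int] = []
    labels: list[int] = []
    prev = 0
    for cut in list(cuts) + [length]:
        if cut <= prev:
            cur ^= 1
            continue
        src = tracks[cur]
        i0 = np.searchsorted(src.ends, prev, side="left")
        if src.ends[i0] == prev:
            i0 += 1
        i1 = np.searchsorted(src.ends, cut, side="left")
        for i in range(i0, i1 + 1):
            seg_end = min(int(src.ends[i]), cut)
            lab = int(src.labels[i])
            if labels and labels[-1] == lab:
                ends[-1] = seg_end
            else:
                ends.append(seg_end)
                labels.append(lab)
        prev = cut
        cur ^= 1
    return _Track(np.array(ends, dtype=np.int64), np.array(labels, dtype=np.int64))


def _autozygous_segments(t1: _Track, t2: _Track) -> list[tuple[int, int]]:
    """Intervals (1-based inclusive) where the two tracks carry the same
    founder-haplotype label."""
    bounds = np.union1d(t1.ends, t2.ends)
    out: list[tuple[int, int]] = []
    prev = 0
    for b in bounds:
        b = int(b)
        lab1 = t1.labels[np.searchsorted(t1.ends, b, side="left")]
        lab2 = t2.labels[np.searchsorted(t2.ends, b, side="left")]
        if lab1 == lab2:
            if out and out[-1][1] == prev:
                out[-1] = (out[-1][0], b)
            else:
                out.append((prev + 1, b))
        prev = b
    return out


def gene_drop(ped: Pedigree, cfg: SimConfig,
              sample_ids: list[str] | None = None) -> tuple[GenotypeMatrix, TruthSet]:
    """Drop founder haplotypes through the pedigree and emit genotypes.

    Each founder (or unknown-parent slot) contributes two uniquely labelled
    haplotypes with alleles drawn from the founder allele-frequency model.
    Meioses recombine under Haldane's model at ``cfg.cm_per_mb``.  A position
    is truly autozygous when both inherited labels match; those segments and
    each individual's true F (IBD length / genome length) are recorded.
    """
    if cfg.markers is None:
        raise ValueError("cfg.markers is required for gene dropping")
    markers = cfg.markers
    rng = np.random.default_rng(cfg.seed + 1)
    chrom_len = chromosome_lengths(markers, cfg.genome_bp)
    chrom_names = list(chrom_len)
    genome_bp = sum(chrom_len.values())
    m = len(markers)
    chrom_of = markers.chrom.astype(str)
    marker_idx = {c: np.flatnonzero(chrom_of == c) for c in chrom_names}

    p_lo, p_hi = cfg.founder_freq_range
    freqs = rng.uniform(p_lo, p_hi, size=m)

    founder_alleles: list[np.ndarray] = []

    def new_founder_haplotype() -> int:
        founder_alleles.append((rng.random(m) < freqs).astype(np.int8))
        return len(founder_alleles) - 1

    # topological order: sort by generation depth
    ids = sorted(ped.ids, key=lambda i: (ped.generation(i), i))
    haps: dict[str, tuple[dict[str, _Track], dict[str, _Track]]] = {}

    def founder_gamete() -> dict[str, _Track]:
        lab = new_founder_haplotype()
        return {c: _Track.uniform(chrom_len[c], lab) for c in chrom_names}

    def meiosis(parent: str) -> dict[str, _Track]:
        h1, h2 = haps[parent]
        out = {}
        for c in chrom_names:
            morgans = chrom_len[c] / 1e6 * cfg.cm_per_mb / 100.0
            out[c] = _recombine(h1[c], h2[c], chrom_len[c], morgans, rng)
        return out

    truth = TruthSet()
    for id_ in ids:
        sire, dam = ped.parents(id_)
        pat = meiosis(sire) if sire is not None else founder_gamete()
        mat = meiosis(dam) if dam is not None else founder_gamete()
        haps[id_] = (pat, mat)

    if sample_ids is None:
        sample_ids = [r.id for r in ped if not r.phantom]
    calls = np.zeros((len(sample_ids), m), dtype=np.int8)
    H = np.array(founder_alleles, dtype=np.int8)
    for i, id_ in enumerate(sample_ids):
        pat, mat = haps[id_]
        segs: list[tuple[str, int, int]] = []
        total_ibd = 0
        for c in chrom_names:
            idx = marker_idx[c]
            pos = markers.pos_bp[idx]
            lab_p = pat[c].label_at(pos)
            lab_m = mat[c].label_at(pos)
            calls[i, idx] = H[lab_p, idx] + H[lab_m, idx]
            for s, e in _autozygous_segments(pat[c], mat[c]):
                segs.append((c, s, e))
                total_ibd += e - s + 1
        truth.ibd_segments[id_] = segs
        truth.true_f[id_] = total_ibd / genome_bp
    gm = GenotypeMatrix(list(sample_ids), markers, calls)
    return gm, truth


# ----------------------------------------------------------------------
# structured populations (Balding-Nichols)
# ----------------------------------------------------------------------

def simulate_structured(n: int, m: int, k: int, fst: float,
                        dirichlet_alpha: float = 0.2, seed: int = 0,
                        markers: MarkerMap | None = None) -> tuple[GenotypeMatrix, TruthSet]:
    """Admixed genotypes with known Q and P.

    Ancestral frequencies ~ Uniform(0.05, 0.95); per-population frequencies
    ~ Balding-Nichols Beta with drift parameter Fst; ancestry rows
    ~ Dirichlet(alpha); genotypes ~ Binomial(2, Q P).
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=m)
    c = (1.0 - fst) / fst
    P = rng.beta(anc * c, (1.0 - anc) * c, size=(k, m))
    P = np.clip(P, 1e-4, 1.0 - 1e-4)
    Q = rng.dirichlet(np.full(k, dirichlet_alpha), size=n)
    F = Q @ P
    calls = rng.binomial(2, F).astype(np.int8)
    if markers is None:
        markers = make_marker_map(m, n_chrom=min(DOG_N_AUTOSOMES, max(1, m // 50)), seed=seed)
    gm = GenotypeMatrix([f"S{i:04d}" for i in range(n)], markers, calls)
    return gm, TruthSet(Q=Q, P=P)


# ----------------------------------------------------------------------
# LD haplotypes and island implants
# ----------------------------------------------------------------------

def simulate_ld_haplotypes(n: int, markers: MarkerMap, decay_bp: float,
                           seed: int = 0) -> GenotypeMatrix:
    """Haplotypes whose allele correlation between markers at distance d is
    exp(-d / decay_bp) (symmetric two-state Markov chain at frequency 0.5);
    two independent haplotypes per individual are summed to dosages."""
    if decay_bp <= 0:
        raise ValueError("decay_bp must be positive")
    rng = np.random.default_rng(seed)
    m = len(markers)
    chrom_of = markers.chrom.astype(str)
    hap = np.zeros((2 * n, m), dtype=np.int8)
    for c in np.unique(chrom_of):
        idx = np.flatnonzero(chrom_of == c)
        pos = markers.pos_bp[idx]
        hap[:, idx[0]] = rng.random(2 * n) < 0.5
        for j in range(1, len(idx)):
            rho = np.exp(-(pos[j] - pos[j - 1]) / decay_bp)
            same = rng.random(2 * n) < (1.0 + rho) / 2.0
            prev = hap[:, idx[j - 1]]
            hap[:, idx[j]] = np.where(same, prev, 1 - prev)
    calls = (hap[0::2] + hap[1::2]).astype(np.int8)
    return GenotypeMatrix([f"S{i:04d}" for i in range(n)], markers, calls)


def implant_island(gm: GenotypeMatrix, region: tuple[str, int, int],
                   seed: int = 0) -> tuple[GenotypeMatrix, TruthSet]:
    """Fix one homozygous haplotype across ``region`` in every individual.

    All samples become homozygous for the same random-but-seeded haplotype
    over the markers inside the region -- a true ROH island.  Re-implanting
    with the same seed is idempotent.
    """
    chrom, start, end = region
    idx = np.flatnonzero((gm.markers.chrom.astype(str) == str(chrom))
                         & (gm.markers.pos_bp >= start) & (gm.markers.pos_bp <= end))
    if idx.size == 0:
        raise ValueError(f"region {region} covers no markers")
    rng = np.random.default_rng(seed)
    hap = (rng.random(idx.size) < 0.5).astype(np.int8)
    calls = gm.calls.copy()
    calls[:, idx] = 2 * hap[None, :]
    out = GenotypeMatrix(list(gm.sample_ids), gm.markers, calls)
    return out, TruthSet(islands=[(str(chrom), int(start), int(end))])
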