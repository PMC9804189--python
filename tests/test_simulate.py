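"""Synthetic-data generators: determinism, demographic regime, and exact truth."""

import numpy as np
import pytest

from breedpop.genotypes import MISSING
from breedpop.pedigree import (
    MALE, Pedigree, PedigreeRecord, clean_pedigree, popular_sires,
    top_sire_contribution,
)
from breedpop.simulate import (
    SimConfig, TruthSet, chromosome_lengths, gene_drop, implant_island,
    make_marker_map, simulate_ld_haplotypes, simulate_pedigree,
    simulate_structured,
)

R = PedigreeRecord


def small_map(n_markers=400, n_chrom=4, genome_bp=120_000_000, seed=0):
    return make_marker_map(n_markers, n_chrom=n_chrom, genome_bp=genome_bp, seed=seed)


class TestPedigreeSim:
    def test_same_seed_identical(self):
        cfg = SimConfig(seed=42, n_founders=16, n_years=6)
        a, b = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert [r for r in a] == [r for r in b]

    def test_output_passes_cleaning_unchanged(self):
        ped = simulate_pedigree(SimConfig(seed=3, n_founders=16, n_years=6))
        cleaned, rep = clean_pedigree(list(ped))
        assert rep.n_year_reset == 0 and rep.n_dob_reset == 0
        assert not rep.removed_links and rep.n_phantom_created == 0
        assert len(cleaned) == len(ped)

    def test_extreme_popularity_concentrates_matings(self):
        cfg = SimConfig(seed=1, n_founders=30, n_years=6,
                        popular_sire_concentration=0.02)
        ped = simulate_pedigree(cfg)
        years = sorted({r.birth_year for r in ped if r.sire_id is not None})
        shares = []
        for y in years:
            cohort = [r for r in ped if r.birth_year == y and r.sire_id]
            if len(cohort) < 20:
                continue
            top = max(sum(1 for r in cohort if r.sire_id == s)
                      for s in {r.sire_id for r in cohort})
            shares.append(top / len(cohort))
        assert max(shares) >= 0.5

    def test_uniform_weights_spread_contribution(self):
        cfg = SimConfig(seed=2, n_founders=60, n_years=4,
                        popular_sire_concentration=50.0, whelp_prob=0.9)
        ped = simulate_pedigree(cfg)
        year = max(r.birth_year for r in ped if r.sire_id)
        contrib = top_sire_contribution(ped, year, n_top=10)
        n_sires_used = len({r.sire_id for r in ped if r.birth_year == year and r.sire_id})
        # with even weights the top-10 share approaches 10/n_sires, far from 1
        assert contrib < 100.0
        assert n_sires_used > 10

    def test_extinction_raises(self):
        cfg = SimConfig(seed=5, n_founders=4, n_years=30, whelp_prob=0.01,
                        mean_litter_size=0.2)
        with pytest.raises(RuntimeError, match="extinct"):
            simulate_pedigree(cfg)


class TestGeneDrop:
    def test_founders_have_zero_true_f(self):
        recs = [R(f"f{i}") for i in range(6)]
        cfg = SimConfig(seed=0, markers=small_map())
        gm, truth = gene_drop(Pedigree(recs), cfg)
        assert all(truth.true_f[f"f{i}"] == 0.0 for i in range(6))

    def test_selfed_founder_offspring_near_half(self):
        # independent founders: each selfing is an independent draw
        recs, kids = [], []
        for i in range(40):
            recs.append(R(f"f{i}", sex=MALE))
            recs.append(R(f"kid{i}", sire_id=f"f{i}", dam_id=f"f{i}"))
            kids.append(f"kid{i}")
        cfg = SimConfig(seed=1, markers=small_map())
        _, truth = gene_drop(Pedigree(recs), cfg)
        fs = [truth.true_f[k] for k in kids]
        se = np.std(fs) / np.sqrt(len(fs))
        assert np.mean(fs) == pytest.approx(0.5, abs=max(3 * se, 0.02))

    def test_full_sib_offspring_mean_quarter(self):
        """Mean true F over independent full-sib families is 0.25 within 3 SE
        of the family means (siblings share parental genomes, so the SE is
        taken across families, not pups)."""
        recs, families = [], []
        for i in range(30):
            recs += [R(f"gs{i}"), R(f"gd{i}"),
                     R(f"f{i}", sire_id=f"gs{i}", dam_id=f"gd{i}"),
                     R(f"m{i}", sire_id=f"gs{i}", dam_id=f"gd{i}")]
            fam = [f"kid{i}_{j}" for j in range(4)]
            recs += [R(k, sire_id=f"f{i}", dam_id=f"m{i}") for k in fam]
            families.append(fam)
        cfg = SimConfig(seed=2, markers=small_map())
        _, truth = gene_drop(Pedigree(recs), cfg)
        fam_means = [np.mean([truth.true_f[k] for k in fam]) for fam in families]
        se = np.std(fam_means) / np.sqrt(len(fam_means))
        assert np.mean(fam_means) == pytest.approx(0.25, abs=3 * se)

    def test_truth_segments_consistent_with_genotypes(self):
        recs = [R("f0")] + [R(f"kid{i}", sire_id="f0", dam_id="f0") for i in range(5)]
        cfg = SimConfig(seed=3, markers=small_map())
        gm, truth = gene_drop(Pedigree(recs), cfg)
        chrom = gm.markers.chrom.astype(str)
        for i, sid in enumerate(gm.sample_ids):
            for c, s, e in truth.ibd_segments.get(sid, []):
                inside = (chrom == c) & (gm.markers.pos_bp >= s) & (gm.markers.pos_bp <= e)
                assert (gm.calls[i, inside] != 1).all()

    def test_ibd_segments_non_overlapping(self):
        recs = [R("f0")] + [R(f"kid{i}", sire_id="f0", dam_id="f0") for i in range(10)]
        cfg = SimConfig(seed=4, markers=small_map())
        _, truth = gene_drop(Pedigree(recs), cfg)
        for segs in truth.ibd_segments.values():
            by_chrom: dict = {}
            for c, s, e in segs:
                by_chrom.setdefault(c, []).append((s, e))
            for ivals in by_chrom.values():
                ivals.sort()
                for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                    assert e1 < s2

    def test_deterministic(self):
        recs = [R("a"), R("b"), R("k", sire_id="a", dam_id="b")]
        cfg = SimConfig(seed=5, markers=small_map())
        g1, t1 = gene_drop(Pedigree(recs), cfg)
        g2, t2 = gene_drop(Pedigree(recs), cfg)
        np.testing.assert_array_equal(g1.calls, g2.calls)
        assert t1.true_f == t2.true_f

    def test_requires_markers(self):
        with pytest.raises(ValueError, match="markers"):
            gene_drop(Pedigree([R("a")]), SimConfig())


class TestStructured:
    def test_deterministic(self):
        a, ta = simulate_structured(20, 100, 3, 0.2, seed=8)
        b, tb = simulate_structured(20, 100, 3, 0.2, seed=8)
        np.testing.assert_array_equal(a.calls, b.calls)
        np.testing.assert_array_equal(ta.Q, tb.Q)

    def test_alpha_to_zero_one_hot_rows(self):
        _, truth = simulate_structured(50, 20, 3, 0.2, dirichlet_alpha=0.001, seed=9)
        assert (truth.Q.max(axis=1) > 0.95).mean() > 0.9

    def test_invalid_fst_errors(self):
        with pytest.raises(ValueError):
            simulate_structured(10, 10, 2, 0.0)
        with pytest.raises(ValueError):
            simulate_structured(10, 10, 2, 1.5)

    def test_q_rows_sum_to_one(self):
        _, truth = simulate_structured(30, 10, 4, 0.1, seed=10)
        np.testing.assert_allclose(truth.Q.sum(axis=1), 1.0, atol=1e-12)


class TestLDHaplotypes:
    def test_long_decay_high_adjacent_r2(self):
        markers = small_map(300, n_chrom=1, genome_bp=3_000_000)
        gm = simulate_ld_haplotypes(100, markers, decay_bp=1e12, seed=11)
        # with effectively no decay each chromosome's haplotype is constant:
        # adjacent markers perfectly correlated wherever polymorphic
        g = gm.calls.astype(float)
        cors = []
        for j in range(0, 20):
            a, b = g[:, j], g[:, j + 1]
            if a.std() > 0 and b.std() > 0:
                cors.append(abs(np.corrcoef(a, b)[0, 1]))
        assert np.mean(cors) > 0.95

    def test_zero_decay_background_r2(self):
        markers = small_map(200, n_chrom=1, genome_bp=20_000_000)
        gm = simulate_ld_haplotypes(60, markers, decay_bp=1.0, seed=12)
        g = gm.calls.astype(float)
        r2s = []
        for j in range(0, 150, 3):
            a, b = g[:, j], g[:, j + 1]
            if a.std() > 0 and b.std() > 0:
                r2s.append(np.corrcoef(a, b)[0, 1] ** 2)
        background = 1.0 / (2 * 60 - 1)
        assert np.mean(r2s) == pytest.approx(background, abs=0.02)

    def test_deterministic(self):
        markers = small_map(100, n_chrom=2, genome_bp=10_000_000)
        a = simulate_ld_haplotypes(10, markers, 50_000, seed=13)
        b = simulate_ld_haplotypes(10, markers, 50_000, seed=13)
        np.testing.assert_array_equal(a.calls, b.calls)


class TestImplantIsland:
    def test_implant_makes_all_homozygous_identical(self):
        markers = small_map(400, n_chrom=2, genome_bp=60_000_000)
        gm = simulate_ld_haplotypes(20, markers, 30_000, seed=14)
        region = ("1", 5_000_000, 7_000_000)
        out, truth = implant_island(gm, region, seed=14)
        idx = ((out.markers.chrom.astype(str) == "1")
               & (out.markers.pos_bp >= region[1]) & (out.markers.pos_bp <= region[2]))
        assert (out.calls[:, idx] != 1).all()
        assert (out.calls[:, idx] == out.calls[0, idx]).all()
        assert truth.islands == [region]

    def test_idempotent(self):
        markers = small_map(200, n_chrom=1, genome_bp=20_000_000)
        gm = simulate_ld_haplotypes(10, markers, 30_000, seed=15)
        once, _ = implant_island(gm, ("1", 1_000_000, 3_000_000), seed=15)
        twice, _ = implant_island(once, ("1", 1_000_000, 3_000_000), seed=15)
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_empty_region_errors(self):
        markers = small_map(50, n_chrom=1, genome_bp=5_000_000)
        gm = simulate_ld_haplotypes(5, markers, 30_000, seed=16)
        with pytest.raises(ValueError, match="no markers"):
            implant_island(gm, ("9", 1, 2), seed=0)


def test_chromosome_lengths_partition():
    markers = small_map(100, n_chrom=4, genome_bp=120_000_000)
    lens = chromosome_lengths(markers, 120_000_000)
    assert sum(lens.values()) == 120_000_000
    assert set(lens) == {"1", "2", "3", "4"}
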