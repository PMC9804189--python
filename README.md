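# breedpop

Population-genetic characterisation of closed, pedigreed dog breeds from two
complementary sources: multi-generation studbook pedigrees and biallelic SNP
genotype panels.  The package is aimed at breed-association analysts and
researchers who need the standard battery of within-breed diversity analyses
— inbreeding from pedigree and from genotypes, runs of homozygosity (ROH),
ROH-island selection scans, between-breed structure, and linkage-
disequilibrium decay — as tested, scriptable building blocks rather than a
chain of one-off tool invocations.

## What it computes

**Pedigree analytics.** Studbooks are cleaned deterministically (impossible
birth years such as 19981 set to unknown, children predating their parents
reset, parentage loops broken by cutting the dam link) and then analysed:
Malécot kinship f(a,b) by the recursive tabular method, the pedigree
inbreeding coefficient F_ped = f(sire, dam), complete generation equivalents
CGE = Σ (½)^g over known ancestor slots, per-generation pedigree
completeness by country, popular sires (≥ 32 offspring), yearly top-10 sire
contribution, generation interval, and litter statistics.

**Genotype QC and merging.** PLINK text PED/MAP panels are merged on exact
(chromosome, position), with dosage flips and strand complements reconciled
and palindromic A/T, C/G markers dropped; QC applies sample call rate,
marker call rate, minor allele frequency, and an exact Hardy–Weinberg test
(enumeration of the conditional heterozygote distribution).

**ROH and genomic inbreeding.** A sliding-window ROH caller (window of 50
SNPs, per-SNP hit-rate threshold, gap splitting, length/density filters)
with presets for SNP-array and WGS densities;
F_ROH = Σ ROH length / 2200 Mb of dog autosome, and the excess-homozygosity
coefficient F_HOM = (O − E)/(L − E).

**ROH islands.** Per-SNP population ROH frequency, islands as maximal runs
of SNPs in the top 1% of that frequency distribution, island intersection
across datasets, and gene lookup from BED annotation.

**Structure and LD.** Identity-by-state distances (1 − IBS), classical
(Torgerson) multidimensional scaling, Saitou–Nei neighbor joining with
Newick output; maximum-likelihood admixture (g ~ Binomial(2, Σ_l q_il p_lj))
fitted by EM with masked-entry cross-validation over k; genotype r² decay
curves with two-regime distance binning.

**Synthetic cohorts with known truth.** A first-class simulation module:
yearly-cohort pedigrees with popular-sire mating, gene dropping with Haldane
recombination that records every true autozygous segment, Balding–Nichols
admixed genotypes with known Q and P, haplotypes with tunable LD decay, and
implantable fixed-haplotype regions (true ROH islands).  Every analysis
stage is therefore testable against exact ground truth.

## Worked example

```python
import numpy as np
from breedpop import simulate as sim, roh, pedigree as pedmod

cfg = sim.SimConfig(seed=7, n_founders=16, n_years=8, whelp_prob=0.25,
                    markers=sim.make_marker_map(50_000, seed=7))
ped = sim.simulate_pedigree(cfg)
print(f"pedigree: {len(ped)} dogs")

sires = pedmod.popular_sires(ped, min_offspring=32)
print(f"popular sires (>=32 offspring): {len(sires)}, top: {sires[0]}")
_, mean_litter = pedmod.litter_sizes(ped)
print(f"mean litter size: {mean_litter:.2f}")
print(f"generation interval: {pedmod.generation_interval(ped):.2f} years")

gm, truth = sim.gene_drop(ped, cfg)
segs = roh.detect_roh(gm, roh.ARRAY)
froh = roh.f_roh_per_sample(segs, gm.sample_ids)
true_f = np.array([truth.true_f_min_length(s, 1_000_000, sim.DOG_GENOME_BP)
                   for s in gm.sample_ids])
print(f"ROH segments: {len(segs)}")
print(f"mean F_ROH: {froh.mean():.3f}   mean true autozygosity: {true_f.mean():.3f}")
print(f"corr(F_ROH, true F): {np.corrcoef(froh, true_f)[0, 1]:.3f}")
```

prints

```
pedigree: 603 dogs
popular sires (>=32 offspring): 5, top: ('D000069', 72)
mean litter size: 6.52
generation interval: 3.70 years
ROH segments: 3969
mean F_ROH: 0.057   mean true autozygosity: 0.057
corr(F_ROH, true F): 1.000
```

The simulated breed has five popular sires (the most prolific with 72
pups), litters of ~6, and after eight years of closed breeding a mean
genomic inbreeding of about 6%, which the ROH caller recovers essentially
exactly (per-dog correlation 1.000 between F_ROH and the true
identity-by-descent fraction recorded by the gene-dropper).

A command-line interface mirrors the library (`breedpop ped|geno|roh|
islands|structure|admix|ld|simulate|all`); every command reads and writes
plain text (PED/MAP, CSV, TSV, BED, Newick).

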