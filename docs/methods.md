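# Methods

This note documents the models, conventions, and numerical choices behind
breedpop, and what the synthetic-data generators do and do not emulate.

## Pedigree model

A pedigree is a directed acyclic graph of parent links.  Kinship is the
Malécot coancestry computed by the recursive tabular method:
f(x, x) = ½(1 + F_x) with F_x the kinship of x's parents, and
f(a, b) = ½[f(sire_a, b) + f(dam_a, b)], recursing on the individual with
the greater generation depth (which therefore cannot be an ancestor of the
other); unknown parents contribute zero.  Results are memoised and exact
(no matrix truncation).  F_ped of an individual is by construction the
kinship of its parents, and the test suite pins the whole recursion against
an independent Wright path-counting oracle.

Cleaning conventions, chosen to be deterministic and idempotent:

* plausible birth years default to [1850, current year]; anything outside
  resets the year and full date to unknown;
* a record whose known parent has a strictly *later* known birth year has
  its own date reset; equal years are tolerated, since twins-vs-typo cannot
  be distinguished at year resolution;
* parentage cycles are broken during a DFS over sorted ids, cutting the
  link that closes the cycle and preferring the dam link (consistent with
  correcting a mis-recorded mother); every cut is reported;
* parents referenced but never declared become flagged phantom founders.
  Phantoms count as *unknown* for completeness statistics (CGE, per-
  generation completeness) but participate normally in the graph.

Demography conventions: a litter is keyed by (dam, full birth date), falling
back to (dam, sire, birth year) when only the year is known — studbooks
rarely define their grouping, so both keys are available.  The generation
interval pools sire and dam pathways unweighted.  Yearly top-sire
contribution re-ranks sires *within each year* (the top 10 of that year's
matings, not the all-time top 10), which is what makes a per-year range of
contributions meaningful.

## Genotypes, merging, and QC

Calls are dosages of the load-time minor allele (0/1/2, −1 missing) over a
sorted, unique (chromosome, position) marker map (1-based, PLINK MAP
convention).  Merging intersects panels on exact location; allele labels
are reconciled against the first panel by dosage flip (swapped labels),
strand complement, or both; A/T and C/G palindromes are unresolvable and
dropped with a count.  A dosage flip changes the counted allele, not the
information: per-marker allele frequencies are invariant, which is asserted
in tests.

QC order (samples first, then variants, mirroring common practice):
sample call rate ≥ 0.95 → marker call rate ≥ 0.95 (recomputed) → MAF ≥ 0.05
→ HWE exact p ≥ 1e−6.  The HWE test is the exact conditional test: given n
genotypes and the minor-allele count, P(n_het) ∝ n!/(n_AA! n_Aa! n_aa!)·2^n_Aa,
two-sided p = Σ of outcome probabilities ≤ the observed one.  No mid-p
correction is applied.  Computation is in log-space via gammaln with a
1 + 1e−12 relative guard when accumulating ties; an exhaustive rational-
arithmetic enumeration over every genotype triple with n ≤ 50 agrees to
1e−12.

## ROH detection

Per sample and chromosome, every window of `window_snp` consecutive SNPs is
called homozygous iff it contains at most `max_het_per_window` heterozygous
and `max_missing_per_window` missing calls.  Windows are never truncated at
chromosome ends, so terminal SNPs belong to fewer windows.  A SNP qualifies
iff (homozygous windows containing it)/(windows containing it) ≥
`hit_threshold`.  Maximal runs of qualifying SNPs are split at inter-SNP
gaps > `max_gap_kb`, then filtered by `min_snp`, `min_kb`, and the inverse
density `length_kb / n_snps ≤ max_density_kb_per_snp` (applied after
splitting).  Segment bounds are the outermost qualifying SNP positions; no
extension into non-qualifying flanks, and no re-filtering of hets inside a
final segment (window-level control only).

Presets: `ARRAY` = (50 SNP window, ≥ 50 SNPs, ≥ 1000 kb, ≤ 50 kb/SNP, gap
≤ 1000 kb, hit ≥ 0.05, ≤ 1 het, ≤ 5 missing); `WGS` = same except ≥ 500 kb,
≤ 30 kb/SNP, ≤ 5 het (sequence calls carry more false heterozygotes), ≤ 3
missing.  The 50-SNP figure is read as *both* the scanning-window size and
the per-segment minimum; both are independently configurable because some
callers distinguish them.  A practical consequence of the density cap: the
ARRAY preset needs ≥ ~1 SNP per 50 kb, i.e. ≥ ~44K markers on a 2200-Mb
genome, or every candidate segment fails the density filter.

The caller is vectorised (cumulative sums over window indicators) and is
pinned, over a thousand randomized parameterisations, to an exhaustive
loop-based oracle that enumerates every window and every SNP's hit rate.

F_ROH divides summed segment length by a fixed 2200 Mb dog autosome (the
denominator is a parameter).  F_HOM is (O_hom − E_hom)/(L − E_hom) per
sample over its non-missing markers, with E_hom = Σ_j [1 − 2p_j(1−p_j)·
T_j/(T_j−1)] using cohort-wide allele frequencies p_j and non-missing
allele counts T_j; markers with T_j < 2 are skipped.

## ROH islands

Per-SNP ROH frequency is the fraction of samples with a called segment
covering the position (a sample counts once however many of its segments
overlap).  The island threshold is the (1 − top_fraction) empirical
quantile, nearest-rank upper variant: the (⌊q·m⌋ + 1)-th order statistic,
capped at m.  For non-integer q·m this is the classic ⌈q·m⌉ nearest rank;
at integer q·m the upper rank is taken so that "top 1%" of 1000 SNPs marks
10 SNPs rather than everything tied at the 990th value.  Ties at the
threshold are all included.  Islands are maximal runs of *consecutive
marked SNPs* per chromosome; their bp span is [first SNP, last SNP], and
sub-threshold gaps are never bridged.  Dataset overlap (e.g. array vs WGS
calls) is plain interval intersection in bp space after independent
calling.  Gene lookup converts BED (0-based half-open) to 1-based inclusive
and requires ≥ 1 shared bp.

## Structure

IBS distance: d = 1 − mean[(2 − |g_a − g_b|)/2] over markers typed in both
samples (pairwise-complete; a pair sharing no typed marker is an error).
Classical MDS is Torgerson scaling: B = −½ J D² J, coordinates are top-k
eigenvectors scaled by √eigenvalue; a negative eigenvalue among the top k
means the distances are not k-Euclidean and is an error rather than a
silent truncation.  Axis signs are fixed (first nonzero loading positive)
for reproducible output.  Neighbor joining is the standard Saitou–Nei
agglomeration with Q_ij = (n−2)d_ij − r_i − r_j, deterministic smallest-
index tie-breaking, and negative branch-length estimates clamped to zero
with a count kept on the tree.  NJ is exact on additive distances, which
the tests exploit (random additive metrics up to n = 8 must be reproduced
to 1e−8 path length), with a topology cross-check against scikit-bio's
implementation.

## Admixture

The model: genotype g_ij ~ Binomial(2, Σ_l q_il p_lj), Q rows on the
simplex, P ∈ [ε, 1−ε] with ε = 1e−6.  Fitting is plain EM on the allele-
origin latent variables (the frappe formulation): responsibilities
a_ijl ∝ q_il p_lj and b_ijl ∝ q_il(1−p_lj), with closed-form Q and P
updates from their sums.  Missing entries are simply omitted from the
likelihood and the updates.  EM is monotone; the ε-clipping can perturb an
update by O(ε), so tests assert non-decrease to a 1e−8 slack.  Block
relaxation (as in the widely used admixture software) optimises the same
likelihood faster per iteration; EM was chosen for its transparency and
provable monotonicity, and agreement is expected in well-separated regimes
though iteration counts differ.  Three seeded restarts (default) guard
against local optima; k = 1 degenerates to sample allele frequencies.

Model choice: masked-entry cross-validation.  Non-missing genotype entries
are partitioned into folds; per fold the entries are set missing, the model
refitted, and the masked dosages predicted as ĝ = 2(QP); the fold error is
the mean squared error and k with the smallest mean CV error wins.  The
reference software scores folds by binomial deviance instead; MSE selects
the same k in separable simulations but is not numerically identical to
that tool's CV column.  Label switching between fits is resolved by
Hungarian assignment on Q-column correlations.

## LD decay

r² is the squared Pearson correlation of dosage vectors over shared
complete cases — the composite (genotype) r², since the package works with
unphased data; haplotype r² would require phasing, which is out of scope.
Pairs are intra-chromosomal within 2000 kb by default; pairs monomorphic in
the complete-case subset or with < 4 shared samples are skipped, and
cohorts of ≤ 3 samples are refused outright (too few genotypes for a
meaningful correlation; tiny breeds are excluded from decay analysis for
the same reason).  The decay curve bins distances left-open right-closed:
fine bins (100 bp) up to a break (2000 bp), coarse bins (3000 bp) beyond,
reporting per-bin mean r² and pair counts; empty bins keep count 0 and an
undefined mean.

## Synthetic data: what it emulates, and what it does not

`simulate_pedigree` grows discrete yearly cohorts: breeding-age females
(2–8 years) whelp with probability `whelp_prob`, litter sizes are Poisson
(default mean 6.1 pups, the regime of a large pointer studbook), and sires
are drawn with probability proportional to a per-male Gamma weight whose
shape (`popular_sire_concentration`, default 0.3) concentrates matings on
a few popular sires.  The output is internally consistent, so cleaning it
is a no-op — useful as a fixture invariant.

`gene_drop` gives each founder two uniquely labelled haplotypes; meioses
recombine under Haldane's model (Poisson crossover count, uniform
positions, no interference) at 1 cM/Mb on 38 equal autosomes totalling
2200 Mb (all configurable).  Haplotypes are piecewise-constant label
tracks in continuous bp, so true autozygosity — both labels identical — is
known *exactly*, not at marker resolution.  Founder marker alleles are
Bernoulli with frequencies ~ Uniform(0.05, 0.95).  Omitted on purpose:
mutation (negligible on studbook timescales), genotyping error (default 0),
interference, sex-specific maps, and coalescent structure among founder
haplotypes.  Consequently background LD between founders is absent, so
false-positive ROH are rarer than in real arrays; passing recovery tests
demonstrates correctness of the machinery, not field error rates.

`simulate_structured` draws population frequencies from the Balding–
Nichols Beta around Uniform(0.05, 0.95) ancestral frequencies with drift
Fst, ancestry rows from Dirichlet(α), genotypes Binomial(2, QP) — matching
the admixture model exactly (sites unlinked).  `simulate_ld_haplotypes`
uses a symmetric two-state Markov chain at frequency 0.5 whose allele
correlation between markers at distance d is exp(−d/decay_bp); mean r²
therefore decays as exp(−2d/decay) toward the finite-sample background
1/(2n−1).  `implant_island` overwrites a region with one seeded homozygous
haplotype in every sample, a maximally strong selection signature with a
known interval.

## Problem sizes in tests and the acceptance script

The validation studies run at sizes chosen to make the statistics stable:
the gene-drop recovery uses a ~250-dog pedigree (16 founders, 8 years) on
50 000 markers / 2200 Mb — the density at which the ARRAY preset is
meaningful — and compares F_ROH against true autozygosity counted in
segments ≥ 1 Mb; admixture recovery uses n = 100, m = 5000, k = 2, Fst 0.1,
and CV model choice n = 60, m = 2000, k = 3, Fst 0.2 over k ∈ 1..5; island
recovery implants 2 Mb on a 100-Mb, 4000-marker genome.  Monte-Carlo
checks of gene-dropping use means over *independent* families with the
standard error taken across families, because siblings share realized
parental genomes and within-family SEs understate the uncertainty.

## Known limitations

* The ROH caller implements one fixed reading of the window criteria;
  other tools trim segment ends or weight hit rates slightly differently,
  so segment-level agreement with any particular external build is close
  but not bit-identical.
* CV error is an MSE surrogate, not the reference tool's deviance.
* The NJ implementation is O(n³) with a Python candidate scan — fine for
  hundreds of leaves, not for tens of thousands.
* Pedigree cleaning trusts recorded parentage apart from the specific
  error classes it repairs; it cannot detect a plausible but wrong parent.
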