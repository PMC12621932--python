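# Methods

## Overview

panelsmith designs reduced-representation genotyping panels: short
amplicons placed on variation hotspots with conserved primer flanks,
spread evenly along the genetic map, specific in the genome, and
filterable to a clean SNP matrix. This note documents the statistical
procedures, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical corner cases.

## Coordinates and containers

All intervals are 0-based half-open everywhere in memory; conversion to
and from 1-based VCF positions and printed map tables happens only in
`panelsmith.io`. Genotypes live in a dense `GenotypeMatrix`
(variants × samples × 2 allele indices, −1 for missing) with per-call DP
and GQ and per-site QD/FS/ReadPosRankSum. An absent INFO annotation is
stored as NaN ("undefined"), never as 0 — the distinction matters for
pass-by-absence filtering. Only GT, DP, GQ, QD, FS and ReadPosRankSum are
interpreted; other VCF content passes through untouched.

## Population-genetic statistics

**Windowed π.** Per site, the probability that two distinct sampled
chromosomes differ is (n² − Σ c_k²)/(n(n−1)) over allele counts c_k with
n non-missing alleles; window π sums these over a non-overlapping 50-bp
tiling and divides by the full window length (monomorphic and missing
positions included in the denominator; no accessibility correction).
Sites with fewer than two non-missing alleles contribute zero and are
counted. Multiallelic sites enter π through the full allele-pair sum; all
other statistics collapse them to major-vs-rest. The estimator is
phase-free: for unphased data it equals the phased average pairwise
difference in expectation, and the window tests use phased toy data where
the equality is exact.

**Tajima's D** uses the standard constants a₁…e₂ for n chromosomes with
D = (k − S/a₁)/√(e₁S + e₂S(S−1)), where k is the summed per-site mean
pairwise difference count and S the segregating-site count over the
region. n is fixed at 2 × (subpopulation size); sites with missing calls
contribute k with their own non-missing allele count. D is null
(undefined, not zero) when S = 0 or n < 4.

**Malecot's f** is a ratio of sums over polymorphic sites,
f = 1 − Σ H_obs / Σ 2p̂(1−p̂)n_geno, clamped to [−1, 1]; null when no
polymorphic site has two genotyped diploids. The ratio-of-sums form keeps
low-information sites from dominating.

**LD r² and pruning.** r² is the squared Pearson correlation of genotype
dosages over pairwise-complete samples (composite, phase-free); zero
variance gives null, which is never treated as exceeding a threshold.
Pruning scans 500-SNP windows advancing by 250, removing a variant whose
r² with any retained earlier variant in the window exceeds 0.01; removal
is global.

**Method-of-moments IBD.** At biallelic SNPs with frequency p (estimated
from all samples unless supplied), the identity-by-state expectations are
P(IBS0|IBD0) = 2p²q², P(IBS1|IBD0) = 4pq(p²+q²), P(IBS1|IBD1) = 2pq.
Z₀ and Z₁ follow by moment matching from the observed IBS0/IBS1 counts,
Z₂ = 1 − Z₀ − Z₁; the Zs are clamped to [0,1] and renormalized and
PI_HAT = Z₂ + Z₁/2. Pairs with fewer than 200 informative sites are null.
No small-sample frequency correction is applied; with ≥ 1,000 sites and
a cohort of ≥ 20 samples the estimator separates duplicates (≈ 1),
parent–offspring (≈ 0.5) and unrelated pairs (≈ 0) cleanly, which is all
the pruning rule consumes.

## Candidate regions and the filter cascade

A core is a maximal run of consecutive windows with π > 0.005 whose total
length is 50–150 bp; it is kept only when the adjacent windows covering
at least 30 bp on each side (one primer footprint, configurable) all have
π < 0.0001. Cores at contig ends are rejected. Each subsequent filter
sets an independent flag on the unfiltered candidate — repeat overlap
(≥ 1 bp of core or flank against the mask, or the FASTA soft-mask when no
explicit repeat track is given), CNV suspicion, selection/inbreeding —
so filter order is irrelevant and the pass set is exactly the zero-flag
candidates. Reruns are bit-identical.

CNV suspicion treats the depth and diversity rules as ceilings: a region
is flagged when mean core depth exceeds 20,000× in *all* retained
samples, or core π > 0.02, or the core carries > 25 SNPs — the signature
of collapsed paralogs, which inflate both depth and apparent
heterozygosity. Samples below 5,000× mean core depth are dropped from
that region's statistics (depth is amplicon-local, so the exclusion is
per-region, not global); a region with no surviving sample fails
outright. The selection filter requires −2 < D < 2 and f < 0.25 in every
labeled subpopulation; a subpopulation with no segregating sites gives a
null D and conservatively fails the region (switchable), since an
invariant target is useless for genotyping anyway.

## Gap-filling selection

The selector's internals are this package's own definition: per set,
chromosome-end sentinels initialize the chosen-position lists; until m
loci are chosen, the widest current cM gap across all contigs is located
and candidates inside it are scored
0.7·(1 − |cm − mid|/(gap/2)) + 0.3·(SNPs/max SNPs), with a uniformly
random (seeded) choice among candidates within ε = 0.05 of the best
score — the ε-randomization is what makes the selection "pseudo-random"
while staying reproducible. Empty gaps fall through to the next widest.
Set i uses seed + i. The best of the n_sets sets is the one minimizing
the maximum cM gap (ties: median gap, then seed); truncation to the final
size repeatedly removes the locus whose removal least increases the
maximum gap. Loci are placed on the map by linear interpolation of the
core midpoint, clamped beyond terminal anchors.

The dimer screen is an explicit stand-in for commercial multiplex design:
a pair is flagged when the 3'-terminal 5 bases of one primer
reverse-complement-match a subsequence of the other (extension-competent
duplex) or any perfect reverse-complement run of ≥ 8 bases exists
anywhere. No thermodynamics (Tm, ΔG, hairpins) are computed.

## In-silico PCR

Primer matching is ungapped (substitutions only) with a budget of
⌊0.05 × length⌋ mismatches — one mismatch for 17–26 bp primers; genome
Ns count as mismatches. Products are convergent plus/minus hit pairs on
one contig, with either primer allowed on either strand, outer span
≤ 300 bp and at least the two primer footprints. "More than one product"
flags putative off-target loci (the count includes the intended target);
zero products is reported separately as target-not-found. The scanner is
vectorized over offsets but is algorithmically the same position-by-
position comparison as the brute-force oracle used in tests.

## Variant-filter cascade

Site hard filters (QD > 5, FS < 60, ReadPosRankSum > −8, strict
inequalities as printed) apply only to SNP records; indels are removed as
non-SNPs. An absent annotation passes (the annotation source leaves
ReadPosRankSum undefined at sites without heterozygous calls, and
failing those would discard valid homozygous-difference sites); the
report counts pass-by-absence records. Genotype masking sets sub-
threshold calls missing without removing records; the GQ bound is
inclusive (≥ 30) in amplicon mode and strict (> 20) in WGS mode,
an asymmetry retained deliberately from the source protocol. Missingness
filtering is a single pass, variants (over all samples) before samples
(over retained variants), no iteration; the report notes whether the
output is a fixed point. Kinship pruning builds a graph over pairs with
PI_HAT > 0.75 and greedily removes the highest-degree sample (ties: more
missing data, then lexicographically later id) until no edge remains;
`keep_related` inverts the rule for technical-duplicate studies. All
stage counts telescope exactly.

## Panel evaluation

Reads are assigned to a locus when ≥ 50% of the read interval overlaps
the locus interval — robust to primer-trimmed read ends; multimap-flagged
reads are tallied but never counted, and reads are conserved across the
assigned/off-panel/multimap/rejected categories. Balancing factors are
clamp(target share / observed share, 0.1, 2.0), with zero-count loci sent
to the upper clamp. Rarefaction subsamples the fixed read pool without
replacement (multivariate hypergeometric; with-replacement sampling would
bias low depths), 100 seeded replicates by default, and reports the mean
proportion of loci at ≥ 10 reads; the observed-depth endpoint is exact by
construction and depths beyond the pool raise rather than extrapolate.
"Genotyped at 10×" is interpreted as ≥ 10 assigned reads, equivalent to
per-base depth for reads spanning the amplicon. Library sizes are
amplicon lengths plus the construct overhead computed from the actual
tail/index-primer sequences, never hard-coded. Microhaplotype extraction
is the only phase-consuming operation: two allele strings per sample per
locus in position order, null (with reason) on any missing call or
unphased heterozygote.

## Synthetic data: what it emulates, and what it does not

The generator is fully deterministic under its seed and plants exactly
the structure the pipeline detects. Defaults (the study conditions for
all tests): two 120-kb contigs; 50 cores of 50/100/150 bp aligned to the
window grid, 5 of them duplication decoys; 10 tandem-repeat TE tracts;
~1 background site per 2 kb at maf ≈ 0.05 kept 150 bp clear of core
flanks; 25 + 25 diploids in two subpopulations plus 5 admixed individuals
drawing each allele from a parent population with probability 0.5;
per-call depth Poisson around 9,000× (doubled in decoys); GQ 60–99;
1% missingness; a linear 50 cM/Mb genetic map.

Core diversity uses a mixed site-frequency spectrum: per 50-bp core
window, one anchor site (maf uniform on [0.2, 0.45]) plus two
low-frequency sites (maf uniform on [0.02, 0.12]). The mix puts the mean
per-site heterozygosity near the neutral-spectrum expectation 1/a₁ ≈ 0.22
so that planted cores are genuinely neutral under Tajima's D, while the
anchor guarantees window π clears the 0.005 core threshold; expected
window π ≈ 0.014, inside the (0.005, 0.02) design band. Subpopulation
frequencies are the shared base frequency jittered on the logit scale
(σ = 0.3), which models drift without turning rare alleles common. Decoy
cores instead carry 30 sites with 90% heterozygote probability and
doubled depth — a collapsed paralog as seen through a short-read caller.
Annotation spiking violates each hard-filter rule in a disjoint 3% of
records with truth labels returned. Read tables draw per-locus shares
proportional to balancing factor × log-normal(σ = 0.5) bias and flag
reads on duplicated loci multimap with probability 0.9.

Deliberately not emulated: recombination and coalescent genealogies
(diversity is planted via per-site frequencies — sufficient for the
frequency-based statistics under test, wrong for haplotype-structure
statistics the package does not compute), base-level sequencing error,
indels, real repeat families, and reference bias. Passing tests therefore
demonstrate the pipeline's mechanics — detection, filtering, selection,
specificity, filtering arithmetic and estimator correctness — not its
yield on any particular real genome, where candidate counts and
off-target rates depend on the organism's diversity and repeat content.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at the synthetic
scale above (≈ 500 variants × 55 samples, 240 kb of genome, panels of
~25 loci, 350→300-marker selection exercised as 30→25 with 3 exclusions)
— large enough for every code path and stable statistics, small enough to
run in seconds. Oracle comparisons use 100 randomized small instances per
statistic at tolerances of 1e-9 (Tajima's D) and 1e-12 (π, r²); Monte
Carlo checks use 3–4 σ bands. Ties in the gap selector break by sorted
candidate order under the seeded RNG; ties in final-set choice by lower
seed; kinship-pruning ties by missingness then sample id. Degenerate
inputs (empty VCFs, all-missing matrices, zero-count loci, contigs
without candidates) return empty results or nulls with recorded reasons
rather than raising, except where the input is unusable (all-zero read
counts, rarefaction beyond the observed pool, maps with fewer than two
anchors).

## Known limitations

- The depth units of the CNV/depth rules (per-region per-sample mean DP)
  assume amplicon-like deep coverage; on shallow WGS the 5,000×/20,000×
  defaults must be reconfigured.
- PI_HAT moment estimates can be biased when cohort allele frequencies
  are estimated from few or related samples; the pruning threshold of
  0.75 is far from the bias regime, but fine relatedness classes should
  not be read off these estimates.
- The dimer heuristic has no thermodynamic model and is calibrated for
  screening, not design.
- `ld_prune` is quadratic per window in pure Python/NumPy; it is sized
  for panel-scale SNP sets (thousands), not whole-genome matrices.
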