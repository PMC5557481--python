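# Methods

This note describes the statistical machinery implemented in `breedscan`,
the synthetic data used to exercise it, the numerical conventions, and the
open design choices and their resolutions.

## Quality control

The QC cascade runs in a fixed order — sample call rate, marker call rate,
MAF, autosome restriction, Hardy–Weinberg — because removal counts depend
on order: each marker rule is evaluated on the matrix surviving the
previous rules, and the `QCReport` counts removals rule by rule so that
input dimensions minus per-rule removals always equal output dimensions
(checked by `QCReport.validate`). All thresholds are strict in the removal
direction: a marker with call rate exactly at the threshold, or MAF
exactly at the floor, is retained. MAF is computed on non-missing calls
only. Platform intensity filters (GenTrain score, AB R mean) cannot be
evaluated on dosage-level data and are reported as *not applicable* rather
than silently skipped.

The Hardy–Weinberg test is the exact conditional test: given the observed
allele counts, the probability of every possible heterozygote count is
computed (log-gamma arithmetic, renormalised), and the p-value is the
summed probability of outcomes no more probable than the observed one.
The default cutoff, 8.0 × 10⁻⁸, is a Bonferroni-style threshold
appropriate to a ~10⁵-marker panel and is taken as a fixed parameter
rather than recomputed from the marker count, since the number of tests
performed upstream of any particular dataset is not knowable from the
data.

## Pedigree inbreeding, kinship and completeness

F and kinship use the standard recurrence on ordered pairs,
`kinship(x, x) = (1 + F(x))/2` and
`kinship(x, y) = (kinship(sire_x, y) + kinship(dam_x, y))/2` with the
recursion descending through whichever argument is generationally younger
(an individual's rank is 1 + max parent rank, so an ancestor always has
strictly smaller rank and the recurrence is well-founded). Memoisation
makes repeated queries cheap without materialising the full relationship
matrix; the tabular method and Wright's path-counting formula are retained
in the test suite as independent oracles and agree to 10⁻¹². One unknown
parent contributes zero identity-by-descent, so founders and half-known
individuals have F = 0. Cycles are detected up front and reported with
the offending path.

Completeness metrics are slot-based: *equivalent generations* sums
(1/2)ⁿ over every known ancestor slot (a repeated ancestor counts each
time it appears), *complete generations* is the deepest generation with
all slots filled, *maximum generations* the distance to the furthest
known ancestor.

## Effective population size from the inbreeding trend

N*e* = 1 / (2 ΔF L). ΔF is annual: ln(1 − F) is regressed on birthdate
expressed in years (days / 365.25), the negated slope is the annual rate,
and multiplication by the generation interval L (default 4.5 years, a
typical value for a managed dog breed) gives the per-generation rate, so
the formula is dimensionally consistent. F = 0 contributes ln(1) = 0 to
the regression; two exclusion variants are supported — a birthdate cutoff
(dropping the oldest, sparsely pedigreed animals) and dropping F = 0
individuals (in deep real pedigrees F = 0 usually flags missing pedigree
depth rather than genuine outbreeding, and retaining such animals biases
the slope toward zero). A non-negative fitted slope yields a flagged,
undefined estimate rather than a negative N*e*.

## LD and LD-based effective size

r² is the squared Pearson correlation of unphased dosage vectors
(composite LD) over the samples called at both loci (pairwise-complete,
not casewise deletion), restricted to syntenic pairs. This matches what
chip data supports without a phasing step; no EM haplotype r² is
attempted. Loci at or below the MAF floor (default 0.1 for N*e* input,
after common practice for this estimator) and zero-variance pairs are
excluded.

Pairs are averaged in half-open distance bins [lo, hi) (a pair exactly at
an edge joins the bin it lower-bounds); default edges are geometric from
1 kb to 50 Mb since short-range LD structure is log-spaced. Each bin's
mean physical distance converts to Morgans at a constant 0.97 cM/Mb (the
canine genome-wide average), and N*e* = (1/r̄² − α)/(4c), with α = 1
ignoring mutation and α = 2 accounting for it; the bin dates to 1/(2c)
generations ago. The optional finite-sample adjustment subtracts 1/(2n)
from the bin mean before inversion. Bins where the inversion is
impossible (adjusted r̄² ≤ 0, or 1/r̄² ≤ α) are flagged, not dropped
silently. The genetic span 33–100 cM is exposed (`RECENT_SPAN_CM`) as the
preset whose bins inform N*e* roughly one generation back.

## Runs of homozygosity

The detector is the classic scanning algorithm: all windows of
`scan_window_snps` (default 50) consecutive SNPs on a chromosome are
classified as hits when they contain at most `max_het_per_window` (1)
heterozygotes and `max_missing_per_window` (5) missing calls; each SNP's
hit proportion is hits / windows covering it, using the true covering
count near chromosome ends (windows never span chromosomes); a SNP is
eligible when that proportion strictly exceeds 5% ("more than"); maximal
runs of eligible SNPs passing both the 100-SNP and 1-Mb filters are
segments, with boundaries at the first/last eligible SNP's bp position.
The 50-SNP window size is the scanning tool's conventional default and is
exposed as a parameter. Note a consequence of the proportion rule: the
one or two outermost SNPs of a genuinely homozygous stretch are covered
mostly by windows that reach into flanking heterozygous sequence, so
detected boundaries can sit a couple of SNPs inside the true stretch;
the test suite pins this behaviour against a direct window-enumeration
re-implementation rather than asserting the planted end-points.

F_ROH divides the summed segment lengths (inclusive bp) by the physical
extent the genotyping panel assays — 2,198,710,490 bp for the
high-density canine chip; synthetic runs substitute the simulated genome
extent. Internal arithmetic is in bp; tabular output reports kb.

Overlapping segments from ≥ 2 individuals form pools by transitive
closure of the "more than 2 shared SNPs" relation; within a pool,
subgroups collect carriers with identical genotype states over the
pool's consensus (shared-by-all) interval, and the pool-vs-cluster
association is a Pearson χ² (no continuity correction) on the
low/high-membership × subgroup table, with any zero margin flagging the
statistic undefined.

## Weir–Cockerham F_ST and the window scan

The per-locus statistic is the unbiased two-population
variance-components estimator: with per-group sample sizes, allele
frequencies and heterozygote frequencies, the among-population (a),
among-individual (b) and within-individual (c) components are computed
and θ = a/(a + b + c). Negative θ (expected for undifferentiated loci
under the unbiased estimator) is retained — truncation at zero would
bias the empirical tail upward. Monomorphic loci, loci with an uncalled
group, and n̄ ≤ 1 cases are flagged undefined and dropped before
windowing rather than treated as zeros.

Windows average per-locus θ over k ∈ {9, 13, 17} consecutive
defined-θ SNPs of one chromosome, keyed by the central SNP (k odd by
construction). The mean-of-θ form is the default; a ratio-of-sums window
(Σa / Σ(a+b+c)) is available as an option. Both an empirical-fraction
tail (top 0.05%, size ⌈fN⌉, ties at the cutoff all included) and an
absolute-count tail are supported, since the correspondence between a
fraction and a count depends on the panel's window total. The union of
the per-size tails is chained into regions wherever central SNPs lie
within 1 Mb; each region reports its maximum window value per size,
omitting sizes that contributed no tail window.

The window-scheme diagnostic compares the dispersion (CV) of physical
spans of fixed-SNP windows against SNP counts of fixed-size tiling
windows; at chip-like density the fixed-SNP scheme is markedly less
dispersed, which is why the scan windows are SNP-counted.

Cohort selection for the scan picks, per cluster, candidates above a
membership threshold (default 0.90) greedily in decreasing membership
order, skipping any candidate sharing a known sire or dam with an
already-selected one (no half-sibs within a cohort), down to a target of
27 per cluster; shortfalls are reported, not fatal.

## Clustering support

Delta-K is the second-difference statistic on a clustering
log-likelihood table: for each interior K, the mean over replicates of
|L(K+1) − 2L(K) + L(K−1)| divided by the standard deviation of L(K)
across replicates (the cited convention; undefined and flagged when that
sd is zero). The clustering itself is out of scope: membership
coefficients are inputs. Marker thinning is deterministic every-nth
selection in genome-wide map order keeping the first marker, so m
markers leave ⌈m/stride⌉ — 117,971 at stride 3 leave 39,324.

## Synthetic data: what it emulates and what it does not

All generators run from one root seed with per-operation child streams
(`numpy.random.SeedSequence.spawn`), so identical configurations are
bit-identical and adding draws to one stage never perturbs another.
Marker maps are evenly spaced with ±30% uniform jitter, 1-based and
sorted; defaults approximate high-density-chip spacing (~50 SNP/Mb).

**Two-cluster panel.** Background loci follow the Balding–Nichols model:
ancestral frequency p uniform on [maf_floor, 1 − maf_floor], cluster
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target background
divergence (default 0.05, the within-breed level that motivates the
package); F = 0 degenerates to shared frequencies exactly. Genotypes are
binomial dosages with a configurable missing rate. Outlier loci are
planted in blocks of 5 consecutive SNPs (window averaging exists
precisely to suppress single-SNP excursions, so a recoverable planted
signal must be regional, as real selection signatures are), and their
cluster frequencies are displaced symmetrically around p by
δ = √(F_out · p(1−p)) with a per-block random sign, which realises the
target divergence exactly. A Beta draw at F = 0.4 was deliberately not
used for outliers: that Beta is bimodal and frequently sends both
clusters to the same extreme, producing "outliers" with no
differentiation at all, which would make planted-signal recovery a coin
flip regardless of the scan's quality.

**Pedigree gene-drop.** Founders carry globally unique haplotype labels;
gametes recombine with Poisson crossovers at 1 cM/Mb; realized
autozygosity (identical labels) is exact ground truth, and labels
collapse to biallelic dosages through founder-haplotype allele
assignments. Mating rules: a closed random-mating line with alternating
(balanced) offspring sexes, and a repeated full-sib line reproducing the
textbook F series 0.25, 0.375, … Birthdates advance by a fixed
generation interval, so the ln(1 − F) regression can be exercised on
known ΔF.

**Wright–Fisher.** 2N haplotypes, random union of gametes, per-interval
recombination probability distance × rate (capped at 1/2), loci started
at frequency 1/2, a final-generation diploid sample, monomorphic loci
flagged. Default 200 generations is enough for the recent-time LD used
by the estimator to equilibrate at N = 100.

What passing these experiments does **not** show: the generators have no
mutation, no sex chromosomes, no realistic breed demography or haplotype
structure beyond summary LD, and the two-cluster panel has no admixture
gradient — real membership coefficients are continuous, not binary. The
experiments validate the estimators' arithmetic and their ability to
recover known signals at realistic marker densities, not their behaviour
under every demographic history.

## Problem sizes in the shipped experiments

The acceptance script and test suite size their simulations to what the
statistics need, not more: the differentiation scan runs at 27 + 27
individuals (the cohort design the scan is meant for) × 60,000 markers
so that the 0.05% tail holds ~30 windows per size and several regions
can coexist in it; LD-based N*e* uses five drift populations of true size
100 with 400 markers on a 10-Mb chromosome; the gene-drop lines use
30 founders × 8–10 generations. All are deterministic given the root
seed.

## Known limitations

- The PED/MAP dialect round-trips exactly only when the coded allele is
  the minor allele (ties break lexicographically); this is inherent to a
  format that does not store which allele is coded.
- Pool subgroup assignment uses the pool's consensus interval; a
  transitive chain of segments with no common core falls back to a
  single subgroup.
- The LD-based N*e* per-bin formula assumes drift equilibrium and linear
  population growth across bins; no bias-corrected regression variants
  are implemented.
- `estimate_ne_from_ld` treats each bin independently; combining bins
  into a demographic trajectory is left to the caller.
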