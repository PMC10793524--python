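# Methods

## Coordinates and containers

VCF entities are 1-based; every interval container (peaks, masks, search
spaces) is 0-based half-open. A point variant at VCF position `p`
occupies `[p-1, p)`; an indel with reference length `L` occupies
`[p-1, p-1+L)`. Interval merging fuses overlapping *and* book-ended
intervals (configurable `gap`, default 0) and carries back-references
from each merged interval to the contributing atlas peaks, which is what
lets a candidate report name the peaks it hit and lets the compound-het
search treat the merged peak as its locus. Strand is ignored throughout:
accessibility peaks are unstranded. Matrices are small dense numpy
arrays with pandas sidecars; at synthetic scale nothing heavier is
warranted.

## Filters

All thresholds are strict inequalities as conventionally printed:
population AF `< 1e-3` (dominant/de novo) or `< 1e-2` (recessive) in
*both* gnomAD and TOPMed, GERP `> 2`, genotype quality `> 20`, het
allele balance `> 0.15`; boundary values fail. Missing population AF
passes (absence from a reference panel is itself evidence of rarity);
missing GERP fails, because conservation is an affirmative requirement
-- a `require_gerp=False` flag waives this for callsets whose indels
lack scores. Allele balance has only the lower bound. A genotype call
failing these filters is treated as *missing* for inheritance logic
rather than deleting the site: it is never a carrier and never a
confirmed non-carrier. Multi-allelic sites are split to bi-allelic
records; spanning-deletion (`*`) alleles are dropped, and for each
retained alt every other allele counts as reference for zygosity, with
the alt depth taken from that allele's AD entry and the reference depth
as the remainder of the total.

## Inheritance searches

De novo calling is a deterministic rule -- affected child het with a
passing call, both parents hom_ref with at most `max_parental_alt_reads`
(default 0) supporting reads -- rather than a likelihood-based caller,
so it is reproducible without genotype-likelihood fields; the threshold
is exposed. Dominant requires every affected member to carry (het or
hom_alt) and no unaffected member to carry; the incomplete-penetrance
variant waives the latter *within the family only*. Homozygous recessive
requires all affecteds hom_alt, each genotyped parent het, and no
unaffected hom_alt. Compound heterozygotes require both parents present
and unaffected (an affected parent makes the mode inapplicable; absent
parents are never approximated by phasing): all unordered pairs of
distinct variants inside the same merged disease peak, child het for
both, one variant carried by the father only and one by the mother only,
both passing the recessive regime.

Cohort-level exclusion removes dominant-broad candidates carried by any
unaffected individual *outside the candidate's family* and
recessive-broad candidates homozygous in any such individual; a
compound-het pair dies with either member. Restricting to other families
is deliberate: within-family carriers are already handled (or
deliberately waived) by the mode searches, and a cohort-wide reading
would annul the incomplete-penetrance mode entirely. Solved pedigrees
are excluded from every search feeding aggregation. Individuals with
more than 75 de novo candidates (strict) are flagged out of enrichment;
pedigrees are additionally screened by a robust z on candidate counts
(median/MAD, default threshold 5).

## Permutation null

Each iteration redraws the peak set with the exact multiset of lengths
and the exact count, placed uniformly in the unmasked genome by
rejection sampling (longest first, default 10^4 attempts per interval,
failure names the stuck length), never overlapping and never crossing a
contig boundary. The variants tested are the post-filter, *pre-overlay*
candidate sets per disease group, with outlier individuals removed. The
empirical p counts permutations whose in-peak count **>=** the observed
count (ties count against significance; the direction of the tie rule is
our documented choice) and is floored at `1/n_iter`, reported as a
strict bound -- 2.0e-4 at the standard 5,000 iterations. The z-score is
`(observed - mean)/sd` over the permuted counts (population SD); a
zero-SD null yields NaN with a warning.

## Peak-to-gene links, DORC, cluster metrics

Correlations are computed across cells or k-nearest-neighbor cell
aggregates (sampled seed cells, Jaccard-overlap cap, deterministic under
seed). Counts per aggregate are depth-scaled to the mean total and
log1p-transformed before Pearson correlation -- the linking framework's
internals are not prescribed, so this standard normalization is our
documented stand-in. Pairs are tested when the peak midpoint lies within
+/- 500 kb of the (strand-resolved) TSS; p-values come from the
t-distribution and BH FDR is computed across all tested pairs
genome-wide (matching a single FDR column in outputs). High-confidence
links need signed `r >= 0.1` (anti-correlated pairs are excluded) and
`FDR < 1e-4`. Rows with zero variance in either the raw or normalized
values are skipped. For gene ranking, each peak is assigned to its
single lowest-FDR gene (ties: smaller |distance|, then lexical id) and
counts are restricted to +/- 50 kb of the TSS; raw counts are reported
and any normalization left to the caller. The DORC score of gene *g* in
cell *c* is `sum_p x_pc / F_c` over linked peaks within +/- 500 kb of
the TSS, where `F_c` is the genome-wide unique fragment total -- hence
invariance under joint scaling of counts and totals.

Cluster metrics use natural-log entropies with `0 log 0 := 0`;
homogeneity (resp. completeness) is defined as 1 exactly when the
conditional entropy H(C|K) (resp. H(K|C)) is zero, and
`V_beta = (1+beta) h c / (beta h + c)` with beta = 1 by default. The
purity denominator is interpreted as the size of cluster *k* (the
printed form is ambiguous), so values lie in `[1/C, 1]`.

## Allelic statistics

The exact binomial test sums point probabilities of all outcomes no more
probable than the observed one, with a relative tie tolerance of
`1 + 1e-7` so floating-point jitter cannot misclassify symmetric
outcomes. SAD standardization divides by the population SD (so raws
{-1, 0, 1} map to z = +/-1.2247, 0 exactly) within each
(sample/cell-type, timepoint) group; indels are standardized against the
same SNV-derived mean and SD, and groups with fewer than two SNVs or
zero SD are flagged rather than scored. The accessibility model itself
is a pluggable scorer interface (sequence -> per-bin coverage); tests
and analyses use analytic motif scorers, and training a neural scorer is
out of scope. The saturation tabulator scores every non-reference base
at every position per sample, skipping non-ACGT reference positions with
a flag.

## Synthetic cohort: what it emulates and what it does not

The generator's defaults define the study conditions: a 10 Mb
two-contig toy genome; 120 peaks per cell type across five cMN cell
types with log-normal lengths (median 500 bp, sigma 0.5 -- plausible
ATAC peak sizes, minimum 50 bp) and 20% of peaks shared across cell
types; 12 trios, 4 dominant and 4 recessive pedigrees (one trio marked
solved); background variants at 2e-4 per bp with Beta(0.3, 60)
population AFs, Hardy-Weinberg founders and within-family Mendelian
transmission; 5% multi-allelic sites, a fraction carrying a spanning
allele; GERP from an equal mixture of N(0, 1.5) and N(3.5, 1); region
classes at genome-like proportions. Plants cover every inheritance mode
inside the correct disease group's peaks; decoys violate exactly one
filter each. Each sub-generator draws from its own CRC-derived RNG
stream, so adding a generator never perturbs the others.

The linked-matrix generator shares a latent factor between each planted
(peak, gene) pair so the latent correlation equals `r_target`, with
log-normal per-cell fragment totals and Poisson counts around
log-normal intensities. Mean counts are deliberately large (300
accessibility / 200 expression) so Poisson measurement noise does not
attenuate the planted correlation: at mean ~30 the realized Pearson r
was ~0.50 for a 0.6 target, which would misrepresent the planted
condition. Linked peaks sit 30 kb from the TSS (inside both the 500 kb
linking and 50 kb ranking windows); distant peaks beyond 500 kb verify
the window.

Not emulated: linkage disequilibrium, recombination, sequence-level
reads, ATAC overdispersion beyond the log-normal-Poisson mixture, or
real pedigree complexity (all families are two-generation). Passing the
planted-truth tests therefore demonstrates the *logic* of the filters
and searches, not robustness to real-data artifacts such as mapping
error, batch effects, or population structure.

## Problem sizes and numerical choices

The test and analysis configurations use the 10 Mb toy genome, ~2,000
variants across 64 samples, 5,000 permutation iterations for headline
runs and 199-iteration x 200-replicate sweeps for null calibration, 500
cells and 12 genes for link recovery (50 seeded replicates), and n <= 25
full enumeration for the binomial oracle -- sizes chosen so every claim
is recomputed from scratch in minutes on one CPU. Determinism: every
stochastic routine takes a seed or Generator; fixed seeds give
byte-identical outputs.

Known limitations: the Fisher-test odds ratio is the sample
cross-product (Haldane 0.5-corrected when a cell is zero), not the
conditional MLE; multi-hit genes require >= 2 distinct linked peaks
(the variant-count reading is available via `min_peaks=1`); the
cell-type map for the rarer phenotype groups (MGJW, combined
ptosis/MGJWS) is a configurable default; ClinVar labels, if present,
are pass-through annotations and never filter.
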