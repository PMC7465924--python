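# Methods

`genedup` implements an SNP-based workflow for deciding whether genebank
accessions with the same or similar names are duplicate holdings.  The
unit of analysis is the *accession*: a conserved seed sample represented
by a small number of genotyped plants (10 by default), carrying
substantial internal diversity because cabbage and its relatives are
outcrossing.  All statistics are computed from biallelic genotype dosages
with complete-case deletion per locus.

## Genotype model and QC

A call is the dosage of the alternate allele (0/1/2) or missing.  Marker
filtering removes, in a fixed order so report counts are deterministic:
markers failing in every individual; markers with a single observed
allele; and markers missing in strictly more than `max_missing_frac`
(default 0.5) of individuals.  Individuals missing strictly more than 40%
of the retained markers are then dropped; an accession left empty is
flagged excluded rather than deleted, and every downstream stage skips
it.  Thresholds are strict ("more than") on both sides, so a marker
missing in exactly half the individuals, or an individual missing exactly
40%, is kept.

Hardy–Weinberg deviations are scanned per accession with a one-degree
chi-square goodness-of-fit test against the expectation from the sample
allele frequency, without continuity correction.  Loci monomorphic within
an accession are skipped and do not enter the Bonferroni denominator,
which is the number of tests actually performed in that accession.  At 10
individuals the chi-square reference is approximate; the calibration
tests therefore use large simulated samples.

## Diversity

Per accession and locus: observed allele count (1 or 2), Nei's gene
diversity `h = 1 − p² − q²` from sample frequencies, and the observed
heterozygote fraction; each averaged over loci with at least one called
genotype.  `h` carries no small-sample correction: the workflow compares
accessions of identical design size (10 plants), so the uniform bias
cancels in comparisons, and the uncorrected definition keeps `h` and
observed heterozygosity on the same scale.  Associations with metadata
use the Pearson product-moment correlation (two-sided p from the t
transform) and Welch's two-sample t-test between holding genebanks.

## Differentiation

Pairwise F_ST is Nei's two-deme G_ST with equal deme weights and
ratio-of-sums multilocus combination:

    h_S,l = (h_A,l + h_B,l)/2,   p̄_l = (p_A,l + p_B,l)/2,
    h_T,l = 1 − p̄_l² − q̄_l²,    F_ST = 1 − Σ_l h_S,l / Σ_l h_T,l

over loci called in both accessions with h_T > 0.  Significance comes
from reshuffling individuals (not alleles) between the two accessions,
preserving sizes and within-individual genotypic association, with
`p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1)` so p is never exactly zero.
Per-pair random streams derive from the master seed and the (sorted)
accession codes, so a pair's result does not depend on which other pairs
are computed, and `stat(A,B) = stat(B,A)` exactly.

Without a sample-size correction the estimator has a known positive bias
for finite samples: two samples of n individuals from one panmictic
population give `E[F̂] = (1/2n)/(2 − 1/2n)` ≈ 0.026 at n = 10.  The test
suite asserts this analytic finite-sample value on null data rather than
pretending the estimator is unbiased.

Shared alleles per locus count the labels observed (frequency > 0) in
both accessions, in {0, 1, 2}, averaged over usable loci.

## Ordination

Accession-level PCA uses the two allele frequencies of each locus as
variables (complete-case columns), mean-centered, unscaled, decomposed by
SVD.  Individual-level PCA uses allele-copy counts with marker-mean
imputation of missing dosages.  Keeping both (perfectly anticorrelated)
allele columns doubles each eigenvalue but leaves score geometry
unchanged.  Components are oriented so the largest-magnitude loading is
positive; numerically null components (singular value ≤ 1e−9 of the
largest) are zeroed so that arbitrary null-space vectors cannot fake
segregation in marker rankings.  A marker's discriminatory score is the
maximum absolute loading of its allele variables on PC1/PC2, with ties
broken by marker ID.

## Subsampling stability

For each accession pair and subset size (10/50/100/500 by default), 1000
replicates draw markers uniformly without replacement and recompute the
multilocus F_ST from the pair's precomputed per-locus components.  The
summary reports the replicate mean, SD, the standard error of the mean
SD/√B, and whether the ±1 SE band contains the full-data value (with
1e−12 slack so exhaustive subsets are not tripped up by summation
order).  Each (pair, size) combination has its own seed-derived stream.

## Panel selection

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM: only double heterozygotes are phase-ambiguous and are split between
coupling and repulsion according to current estimates; iteration stops
when the largest frequency change falls below 1e−8 or after 200 rounds,
making D′ reproducible to at least six decimals.  D′ = |D|/D_max with the
standard bound; D = 0 maps to D′ = 0.

Selection is greedy in decreasing discriminatory-score order: accept a
marker iff its pooled-sample h exceeds 0.3 (strict) and its D′ against
every already-accepted marker stays below 0.25 (strict).  The pooled
sample is used for h because the panel targets future accession sets.
Rejections are logged with reasons.  On strongly structured collections
the pooled sample carries substantial LD even between physically
unlinked markers (frequency covariance across accessions), so the greedy
rule can exhaust its candidates well short of the requested size; that
outcome is a shorter panel with a warning, not an error.

## Regeneration drift

A regeneration cycle is modelled as a monoecious Wright–Fisher bottleneck
of census size N (random mating with selfing), for which the expected
heterozygosity follows `H_t = (1 − 1/2N) H_{t−1}` exactly.  Ten cycles at
N = 20 retain (1 − 1/40)¹⁰ ≈ 0.776 — a 22% expected decrease.  The
simulator draws the next generation's 2N allele copies binomially per
locus and tracks the expected heterozygosity 2p(1−p), matching the
recursion; cabbage self-incompatibility would push the effective size
slightly below census and is deliberately out of scope.

## Synthetic data

The generator produces the structure the analysis assumes, with known
latent truth for oracle-style tests.  Defaults mirror the study design:
10 name groups holding 5/2/2/4/2/3/3/2/2/2 accessions (27 in total), 10
individuals per accession in HWE, 2000 markers with founder frequencies
uniform on [0.05, 0.95], 5% missing calls at random, acquisition years
1930–1997 with a regeneration cycle every 6 years at N = 50, and two
duplicate links (a pair sharing frequencies up to 5 extra drift cycles).

Divergence is hierarchical Balding–Nichols: group frequencies are Beta
around the founder, accession frequencies Beta around their group.
Because the pipeline's estimator compares two demes against their own
pooled mean — expectation F/(2−F) for raw Balding–Nichols F — the
generator calibrates the Beta parameter as F′ = 2F/(1+F), so a configured
`f_acc` equals the expected pairwise F_ST between sibling accessions at
large sample size (small positive finite-sample bias remains, ≈0.02 at
n = 10).  Defaults `f_group = 0.12`, `f_acc = 0.10` plus age drift put
the within-group mean near 0.16 and the between-group mean near 0.28,
the regime reported for real same-name cabbage accessions.  Loci already
fixed in a parent stay fixed in its children.

What the generator does *not* emulate: physical linkage (markers are
exchangeable, so map positions carry no LD), selection and gene flow
during regeneration, genotyping batch effects beyond a uniform per-call
replicate error, and informative missingness other than the optional
per-chromosome total-failure table.  Passing tests therefore demonstrate
the statistical machinery under the assumed model, not robustness to
those real-data complications.

## Duplicate verdicts

A same-name-group pair is a candidate duplicate iff its F_ST lies at or
below the 10th percentile of all pairwise values *and* its shared-allele
average at or above the 90th percentile — percentile thresholds keep the
judgement relative to the collection, mirroring how similarity "compared
to the average" is assessed in practice, and make the candidate set
nested in the F_ST percentile.  An accession whose nearest neighbour by
F_ST lies outside its name group while a group partner exists is flagged
as a name outlier.  Externally supplied morphology p-values are echoed
into the evidence list but never enter the rule.

## Problem sizes and determinism

Tests and the acceptance script run the generator at its default design
(27 accessions × 10 plants, 2000 markers, 1000 permutations, 1000
subsampling replicates); unit tests use smaller fixtures.  Every random
stream descends from a single seed; re-running any stage with the same
inputs and seed reproduces byte-identical outputs.

## Known limitations

- The F_ST estimator is intentionally uncorrected for sample size; its
  values are comparable within a study of fixed design but carry the
  ≈0.026 panmictic floor at n = 10.
- The chi-square HWE test is approximate at 10 individuals; exact tests
  are out of scope.
- D′ is computed on the pooled sample, so the panel inherits the
  collection's structure; a panel chosen from one collection may be
  suboptimal for another.
- Percentile-based verdicts assume most pairs are not duplicates; in a
  collection dominated by duplicates the thresholds would need absolute
  anchoring.
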