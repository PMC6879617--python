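# Methods

## Model

### VAF–TCF mapping

For a heterozygous somatic mutation observed at variant allele frequency
`v` in a region with total copy number `TCN` and minor allele-specific
copy number `AsCN`, the tumor-cell fraction carrying the mutation is

| region           | TCF(v)              | condition                  |
|------------------|---------------------|----------------------------|
| copy-neutral     | 2·v                 |                            |
| deletion         | TCN·v               |                            |
| UPD, late UPD    | 2·v − 1 + AsCN      | v > (1 − AsCN)/2           |
| UPD, late mut.   | 2·v                 | v ≤ (1 − AsCN)/2           |
| gain             | 3·v                 | TCN fixed at 3             |

Assumptions: exactly one mutated copy except when a UPD duplicated the
mutant allele; the gained-region TCN is unidentifiable from depth and is
fixed at 3 by convention. The two UPD branches are discontinuous at the
threshold; the boundary itself is assigned to the early-mutation branch,
which is continuous with the copy-neutral case, and each call records the
branch used and whether the raw value was clamped to [0, 1] (the gain
formula exceeds 1 for v > 1/3). The mapping is implemented exactly as
stated rather than smoothed: the discontinuity is a property of the
published algebra and is surfaced for audit instead of being silently
repaired.

### Dirichlet-process Beta-Binomial clustering

Per patient, mutation `n` contributes alt reads `a_n` of depth `d_n`.
Cluster assignments follow a Dirichlet process with concentration 1 and a
Beta(1, 1) base measure over cellular prevalence φ. The emission is
BetaBinomial(d_n, ξ_n, s) with mean ξ_n = clip(VAF_expected(φ, cn_n),
ε, 1 − ε), where VAF_expected inverts the TCF branch of the mutation,
ε = 0.001 is the error-rate floor, and the precision has prior
s ~ Gamma(shape 1.0, rate 0.001).

Sampling: Neal's algorithm 8 (3 auxiliary components) for assignments,
random-walk Metropolis for each cluster's φ (step 0.05, proposals outside
(0, 1) rejected), log-scale Metropolis for s (step 0.4). Chains start
from one singleton cluster per mutation at its inverted-VAF prevalence,
which makes the merge-dominated early phase mix quickly at panel depths.
Defaults are 10,000 iterations with 1,000 burn-in; the test and
acceptance workloads run 2,000/200, which changes label agreement on the
recovery fixtures by well under 2 percentage points.

Consensus: the posterior co-assignment matrix is clustered with average
linkage on 1 − similarity and cut at the cluster count maximizing the
posterior expected adjusted Rand index (PEAR). This is a reproducible,
tuning-free stand-in for an unparameterized dynamic tree cut. Clusters
whose posterior mean prevalence falls below the error-rate floor are
merged into their nearest neighbour (numerical guard only).

Labels: the cluster with the highest posterior mean prevalence is the
dominant (ancestral) clone — ties break by member count, then smallest
canonical mutation coordinate, and are flagged as candidate co-dominance;
a `largest_by="members"` option provides the alternative "largest clone"
reading. Mutations excluded from the sampler (indels, repetitive
regions — flagged via an `excluded` column) are labeled post hoc by
nearest prevalence so that association analyses see every call.
Mutations are canonically ordered by (chrom, pos, ref, alt) before
seeding, making results invariant to input row order; cohort fits derive
per-patient seeds from the master seed and the patient identifier, so
results are also invariant to patient order.

### Digital copy number

Per-exon depth sums are standardized per sample to total k₀ = 1. The
reference for sample `s` is the mean standardized profile of the m₀ = 12
normals most Pearson-correlated with `s`; the copy ratio Cn = D/D̂ is
computed on exons with raw mean depth > 500. Because the fixed-sum
standardization couples a true CNA into a small opposite shift of every
other exon in the same sample, the ratio profile is divided by its median
(configurable) before segmentation, so the copy-neutral majority sits at
1. Segmentation is a self-contained circular binary segmentation:
recursive binary splitting at the circular arc maximizing the two-sample
t statistic, kept when a 1,000-permutation test gives p ≤ 0.01, minimum
segment width 2 exons, seeded. Calls use the cohort distribution of
segmented ratios per exon: strictly beyond mean ± 4 SD ⇒ loss/gain (a
value exactly at the boundary is neutral; zero-SD exons are neutral
unless a value deviates, which is flagged degenerate). Losses translate
to deletion (TCN 1, AsCN 0) and gains to TCN 3; UPD is invisible to depth
and must come from SEG input.

### Association statistics

All associations are 2×2 tables over patients. The reported odds ratio is
the cross-product (a·d)/(b·c), +∞ when b·c = 0 with a·d > 0 (the
convention that keeps degenerate perfect associations printable); a
conditional-MLE estimator is available for cross-checking, as published
pair tables mix the two rounding conventions. P-values are two-sided
Fisher exact tests under the point-probability convention; q-values are
Benjamini–Hochberg over all tests run together (one family per call).
Frequency thresholds (> 1% of patients for dominant/secondary pair
candidates, > 2% for lesion–lesion correlation) are strict. Pair
discovery flags q < 0.01; lesion correlation uses the asymmetric
q < 0.01 (coexistence) / q < 0.25 (exclusion) thresholds. Phenotype odds
ratios support single-lesion, rank-restricted, and both-vs-neither pair
groupings (partial carriers dropped in pair mode); confidence intervals
are Woolf log-OR ± 1.96·SE with Haldane 0.5 correction applied to the CI
only. Secondary AML patients enter the MDS vs MDS/MPN dichotomy through
an optional `antecedent` clinical column; without it they are excluded
from that dichotomy.

### CH classification and survival

A patient is CH-related if any dominant mutation hits DNMT3A, TET2,
ASXL1, or JAK2; Overlapping if all dominant genes lie in {TP53, SF3B1,
SRSF2, GNB1, CBL} or if there are no mutations; CH-unrelated otherwise.
Precedence for mixed dominant sets (any CH-related gene wins; otherwise
any out-of-set gene makes the patient CH-unrelated) follows the "at least
one" reading of the class definitions and is deterministic. Survival uses
the Kaplan–Meier product-limit estimator (median = earliest time with
S(t) ≤ 0.5, Greenwood variance), the k-group log-rank test, and
univariate Cox regression with Efron tie handling; monotone-likelihood
fits are flagged non-estimable rather than reported. VAF strata cut at
0.4 with the boundary in the low stratum; patients with several mutations
in the stratifying gene use their maximum VAF.

## Synthetic cohort

The generator emulates the study's data structure: patients carry 1–7
clones (weights peak at 1–2 clones, ~52% single-clone); prevalences are
nested (founder ~Beta(5, 2), each child a Uniform(0.30, 0.85) fraction of
its parent; an option adds one branching event with siblings constrained
to fit inside the parent). Each clone holds 1 + Poisson(0.3) mutations
drawn without replacement within a clone from the packaged 36-gene panel,
with separate dominant/secondary draw weights reflecting each gene's
propensity to initiate vs. to join a clone. Depths are negative binomial
(mean 796, size 8 ⇒ CV ≈ 0.37) truncated at the read-support floor of 20;
alt reads are Binomial(depth, expected VAF) with the expected VAF flowing
through the TCF branch of any overlapping lesion (del(5q) at 16%,
−7/del(7q) at 10%, a 4q UPD at 4%; founder-clone mutations inside a UPD
use the late-UPD branch). Phenotypes are logistic with configurable
dominant→secondary pair effects around base rates matching the cohort
composition (MDS/MPN ≈ 12%, higher-risk ≈ 42%); survival is exponential
with multiplicative group hazards (base 0.026/month ⇒ median ≈ 27 months)
under independent Uniform(0, 120) censoring; HMA treatment is Bernoulli
(10%) with logistic response around a 32% wild-type rate and per-gene
effects (TET2 +0.88 log-odds, ASXL1 −0.70). One seeded generator drives
everything, so identical seed and config give bit-identical cohorts.

What the generator does **not** emulate: positional hotspots and
trinucleotide context, subclonal copy number, correlated censoring,
measurement artifacts beyond a flat 1% unidirectional-read rate, and the
real cohort's gene–gene dependence beyond the configured pair effects.
Passing recovery tests therefore demonstrates estimator correctness under
the stated generative assumptions, not performance on real sequencing
data.

## Numerical choices and problem sizes

- Beta-Binomial likelihoods are computed via log-Γ identities with the
  precision entering as α + β = s, avoiding special-function overflow at
  panel depths.
- Acceptance-scale workloads: clone recovery uses 20 seeded two-clone
  patients (5 + 5 mutations, prevalences 0.8/0.3, depth 600) at 2,000
  iterations; null calibration uses 50 seeds × 2,000 patients with 8
  dominant and 8 secondary candidate genes at 10% carrier rates; CNA
  recovery uses 20 seeds × (60 exons, 40 normals, 10-exon deletion at
  0.5×, CV 5%). These sizes were chosen as the smallest at which the
  binomial/permutation noise floors sit well below the acceptance margins.
- The Fisher oracle sweep enumerates one representative per symmetry
  class (row swap, column swap, transpose leave the p-value invariant) of
  all 2×2 tables with total ≤ 60.

## Known limitations

- Two-level hierarchy only: the reduction to dominant/secondary discards
  deeper topology, and co-dominant clones are reported as a tie flag, not
  a third label.
- The emission uses total copy number through the branch mapping rather
  than marginalizing over mutational genotypes; allele-specific copy
  number from depth alone is out of scope.
- The digital CNA caller assumes a majority of copy-neutral exons per
  sample (median recentering) and cannot see copy-neutral LOH.
- Printed odds ratios in the packaged pair-count fixture mix cross-product
  and conditional-MLE rounding; regression tests accept either estimator
  at one decimal, and rows with an empty co-occurrence cell are checked by
  direction only.
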