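# Methods

`raregene-ipwc` screens genes for association with disease traits when the
signal may be carried by multiple rare variants. Instead of collapsing a
gene's genotypes into a univariate burden score, it collapses them into a
*partition* of the individuals and tests partition–trait association. This
note records the model, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Similarity model

For a biallelic SNP with minor allele *a* at frequency *p* (and major
allele *A* at 1 − *p*), the allelic similarity of two observed alleles *x*,
*y* is the inverse-probability score

    score(x, y) = 1{x = y} / p_x − 1,    p_a = p,  p_A = 1 − p.

A match on the rare allele earns (1 − p)/p, a match on the common allele
earns only p/(1 − p), and any mismatch costs 1. The expectation under two
independent allele draws at (p, 1 − p) is exactly 0 for every p, so a gene's
summed similarity is centred regardless of its MAF composition, while
sharing a rare allele is overweighted in inverse proportion to its
frequency — the property that lets a handful of rare-variant carriers
dominate the clustering of a gene.

The genotypic score of two individuals at one SNP is half the sum of the
allelic scores over the four cross-pairs of their alleles; e.g. *aa*
against *aA* contributes exactly one (*a*, *a*) match and one (*a*, *A*)
mismatch. Under Hardy–Weinberg genotype frequencies
(p², 2p(1 − p), (1 − p)²) for two independent individuals, its expectation
is again identically 0 (tested in closed form to 1e−12 and by Monte-Carlo).

Gene-level similarity is the sum of the per-SNP genotypic scores over the
SNPs of the gene, using the *sample* MAF of the analysed matrix (no
external frequency panel). Monomorphic columns are excluded: at p = 0 the
score is undefined, and such SNPs carry no pairwise information.

## Distance transform and clustering

Similarities are mapped to dissimilarities with

    d(i, j) = exp(−sim(i, j) / a),    a = max(1, max_{i<j} |sim(i, j)| / 20),

so off-diagonal distances always lie in [e^−20, e^20]; the per-gene
normaliser `a` makes genes with very different SNP counts comparable, and
its floor at 1 avoids blowing up near-zero similarities in genes with
little variation. The diagonal is forced to 0.

Individuals are clustered by Ward's minimum-variance criterion. Because the
input is a transformed similarity rather than a Euclidean embedding, the
Lance–Williams Ward recurrence is applied to the distances as-is (the
"ward.D" convention; "ward.D2", which squares them, is available via
`ward_dialect`). Internally the merge order is obtained from scipy's
squared-input Ward applied to the square roots of the distances — an exact
reproduction of ward.D ordering, since the square root is monotone — and
heights are transformed back. Partitions are obtained by cutting the tree
into a prespecified number of groups K (default sweep K = 5…10), never at a
height, so the occasional height inversion possible on non-Euclidean input
cannot affect results. Cuts are nested (the K-cut refines to the (K+1)-cut)
and deterministic; labels are renumbered 1..K by first appearance. When a
gene offers fewer distinct genotype profiles than K, K is capped at the
number of profiles and the result is flagged.

## Association statistics

Given a partition with element sizes n_i and a trait y:

* **Partition retention I** = Σ_i n_i² (ȳ_i − ȳ)² / (n s²), with ȳ_i the
  element means and ȳ, s the overall mean and standard deviation (s² uses
  denominator n; the n − 1 alternative differs by O(1/n) and is not
  exposed). I applies unchanged to quantitative and 0/1 traits, is
  invariant to affine transformations of y, and is 0 for constant traits.
  Under the null it converges to a weighted sum of 1-df chi-squares with
  mean 1; its exact null mean for i.i.d. traits is 1 − Σ_i n_i²/n², which
  the test suite and the acceptance script verify by simulation. I is used
  with a rank-based selection rule (top fraction of genes, default 0.1%
  with ceiling rounding so at least one gene is always selected, ties
  broken by gene id), not with a p-value.
* **One-way ANOVA**: classical F on (K − 1, n − K) df with the asymptotic
  p-value; dichotomous traits are treated as numeric 0/1. Zero pooled
  within-group variance with unequal means is reported as F = ∞, p = 0 with
  a flag rather than an error.
* **Pearson chi-square** of independence on the 2 × K table of a 0/1 trait
  against the partition, df = K − 1, no continuity correction; any expected
  cell below 5 (Cochran's rule) raises a `sparse` flag because the
  asymptotic p is then unreliable — the partition-retention measure is the
  robust alternative in that regime. A constant trait (zero row margin)
  yields statistic 0, p = 1, flagged degenerate.
* **Fisher's exact test for 2 × c tables** (diagnostics, e.g. crossing a
  partition with a single SNP's genotypes): two-sided by probability-mass
  ordering — the p-value sums the multivariate hypergeometric probabilities
  of all margin-consistent tables no more probable than the observed one
  (relative tie tolerance 1e−7, as in standard exact-test practice).
  Enumeration is direct over the first row with log-gamma arithmetic;
  for the 2 × 5 cohort-scale tables used in diagnostics this is well under
  a second.

Permutation p-values (trait permuted across individuals, p = (1 + #{perm ≥
obs}) / (1 + B), seeded) are available for any statistic as the recommended
small-sample alternative to the asymptotic distributions.

## The screen

Per gene: filter SNPs (all, or nonsynonymous-only — SNPs whose synonymy is
unknown are conservatively excluded from the nonsynonymous set), compute
similarity, distance, the Ward tree, cut at each K, and test each
(trait, method, K). Across genes, selection is applied per screen — one
(trait, method, K, replicate) family — with Bonferroni n_tests equal to the
number of genes in that screen for the p-value methods, or the top-fraction
rule for I. Aggregating over K averages the per-K selection counts (the
partition size giving the strongest signal varies from data set to data
set, so no single K is privileged); a `best_k` aggregation mode that judges
each gene at its most significant K is available behind the config switch.
Gene-wise effect size is Σ_i MAF_i β_i over the gene's SNPs (0 for
noncausal genes), and the power curve tabulates detection frequency against
it.

## Synthetic mini-exome

The simulator emulates the shape of a GAW17-style benchmark: 697 unrelated
individuals (209 cases / 488 controls), 3,205 genes by default, ~7.6 SNPs
per gene (1 + negative binomial with dispersion 1.5, giving the long right
tail of real gene sizes), and a MAF spectrum with 74% of SNPs rare
(MAF < 1%). Rare MAFs are drawn log-uniform on [1/(2n), 0.01) to populate
the very-rare tail (< 0.5%); common MAFs uniform on [0.01, 0.5]. Genotypes
are Hardy–Weinberg draws, independent across SNPs. Because the 74% figure
describes the *observed* spectrum and binomial sampling of 2n = 1394
alleles blurs the 1% boundary, each column is redrawn (up to 30 times)
until its realized sample MAF falls on the drawn side of the boundary;
persistently monomorphic SNPs are dropped. Dosages are folded to count the
sample minor allele.

Phenotypes: each quantitative trait is Σ_i β_i · dosage_i plus N(0, sd)
noise redrawn per replicate over the fixed genotypes (200 replicates by
default); Affected status thresholds a liability — a designated
quantitative trait plus independent N(0, sd) noise — at its
(1 − case fraction) sample quantile, so every replicate has exactly
round(case_fraction · n) = 209 cases by construction. This linear-additive
liability-threshold model is the simplest generator consistent with
per-SNP effect sizes and a fixed case/control split; it does *not*
reproduce any particular benchmark's trait architecture.

Deliberately absent from the default generator: linkage disequilibrium,
haplotype structure, pedigrees, and population stratification. An optional
two-subpopulation mode (Balding–Nichols frequency divergence at a given
Fst) reproduces qualitatively the "consistent false positive" phenomenon
that structured samples induce. Consequently, passing the synthetic
benchmarks demonstrates calibration and power behavior under independent
HWE genotypes — not robustness to LD or admixture, which in real data
require external stratification adjustment before this screen is run.

A planted fixture (one gene, one rare SNP carried heterozygously by a
designated set, default three common background SNPs) provides the
ground-truth check that carriers of a rare variant are isolated in a
single partition element across the K sweep.

## Problem sizes used in the checks

The shipped checks run the screen at reduced but structurally faithful
scale, chosen so the full suite completes in a couple of minutes on one
core: null-screen calibration uses 300 genes × 100 replicates (ANOVA on a
quantitative trait, per-screen Bonferroni at 0.05); power monotonicity uses
60 genes of which 10 are causal with gene-wise effects geometrically spaced
over 0.005–0.15 (chosen a priori to span negligible-to-near-certain
detection at n = 697) × 30 replicates; the null mean of I uses n = 2000
with 10,000 trait replicates. The acceptance script
(`scripts/acceptance.py`) recomputes the two headline calibration
quantities — the null mean of I on a 40-element equal partition of 2000,
and the closed-form HWE expectation of the genotypic score at p = 0.01 with
a 10⁶-pair Monte-Carlo guard — from scratch at every invocation.

## Known limitations

* The similarity scores are defined for complete biallelic dosage data;
  missing genotypes are rejected, not imputed.
* Sample-MAF weighting makes scores dataset-dependent: the same pair of
  individuals can score differently in different cohorts.
* The chi-square and ANOVA p-values are asymptotic; with the sparse
  partitions rare-variant genes produce, the flags should be heeded and
  permutation p-values used for final inference.
* Ward tie-breaking follows scipy's deterministic nearest-neighbor-chain
  order; results are reproducible for identical input, but exotic exactly
  tied inputs may partition differently across scipy versions.
* The top-fraction rule always selects at least one gene per screen; on a
  fully null exome this is by design a forced discovery, which is why
  family-wise calibration is assessed with the Bonferroni methods.
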