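# Methods

This note documents the statistical models implemented in `msatpop`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Genotype model

Genotypes are unordered pairs of positive integer allele labels (raw
fragment sizes in bp; the package does no binning — sizing is upstream of
its scope). Missingness is genotype-level: a half-called genotype (one
known allele) carries ambiguous information under every statistic computed
here, so it is coerced to fully missing with a warning rather than given a
special code. Individuals missing at a locus are dropped for that locus
only (pairwise deletion) in every estimator.

A matrix can carry several named groupings (e.g. phenotype and zone) at
once. GENEPOP can express only one grouping, so the delimited table is the
lossless native format and GENEPOP export takes a grouping name. Writers
are deterministic byte-for-byte.

## Diversity statistics

- **He** defaults to Nei's unbiased gene diversity
  `2n/(2n−1)·(1 − Σp²)`; the uncorrected form is available by flag. The
  correction matters at the small per-phenotype sample sizes (n = 5–20)
  this package targets.
- **Allelic richness** uses hypergeometric rarefaction,
  `AR(g) = Σ_a [1 − C(2N−N_a, g)/C(2N, g)]`, the expected number of
  distinct alleles among g gene copies drawn without replacement. The
  closed form is verified in the test suite against exhaustive subsample
  enumeration for all spectra with 2N ≤ 8. The rarefaction size g is the
  smallest gene-copy count over the non-empty cells of a chosen grouping
  and is computed **per grouping**: whole-sample AR, per-phenotype AR and
  per-zone AR each rarefy to their own g, because a whole-sample g would
  make AR collapse to Na. Which grouping sets g for the whole-sample table
  is exposed as a parameter (`rarefaction_grouping`), since small-cohort
  reports differ in this convention.
- **PIC** uses Botstein's formula with the pairwise term evaluated as
  `(Σp²)² − Σp⁴`.
- In `mean ± SD` footer rows, SD is the standard deviation (ddof = 1) of
  the listed values themselves — across loci in the per-locus table,
  across loci within a population in the per-population table. Cells with
  zero genotyped individuals are excluded from averages with a logged
  warning.

## Weir–Cockerham F-statistics

The variance components a, b, c are computed per allele from the weighted
sample sizes, allele frequencies and heterozygote frequencies (the
`wc_components` docstring spells out the exact expressions). Multilocus
estimates are **ratios of summed components**, not means of per-locus
ratios — the estimator's recommended combination, under which the identity
`(1 − F) = (1 − f)(1 − θ)` is exact by construction; the test suite checks
it to 1e-12 together with an independent, deliberately loop-based
re-evaluation of the same formulas.

Per-population F_IS uses the multilocus ratio-of-sums form
`1 − ΣHo_l / ΣHe_l` with unbiased He. Legacy desktop programs differ in
their per-population estimator (per-locus weighting schemes vary and are
rarely documented), so third-decimal agreement with any specific program is
not claimed.

The permutation test for heterozygote deficit shuffles the 2n gene copies
among individuals within the population, independently per locus. Allele
frequencies — hence He — are invariant under this shuffle, so only Ho is
recomputed. The permutation pool is rebuilt from the allele-count spectrum
(heterozygosity under random pairing depends on labels only through their
counts), which makes the p-value exactly invariant to allele relabeling.
The p-value uses the +1 correction, `p = (1 + #{F_IS* ≥ F_IS}) / (1 + n)`,
one-sided for deficit. Significance is plain per-test α = 0.05; no
multiple-testing correction is applied (none is standard in the table
layout this mirrors). Type-I error is verified by simulation (≈5% over 200
panmictic datasets).

## Nei identity and distance

J-statistics are averaged **across loci first** and the ratio taken
afterwards (the POPGENE convention), with the unbiased within-population
homozygosities `(2nΣp² − 1)/(2n − 1)`. Loci typed in only one population of
a pair are dropped pairwise. At very small n the unbiased correction can
produce Ĵ ≤ 0 (locus excluded, logged) or I > 1; I > 1 is reported as-is
with D = −ln I < 0, logged and never clamped, so that small-sample outputs
remain faithful to the estimator.

## Neighbour-Joining

Standard Saitou–Nei agglomeration. Determinism: ties in argmin Q are broken
by the lexicographically smallest pair of (smallest-contained-leaf) labels,
and Newick children are ordered by smallest contained leaf. Negative branch
lengths are kept by default (faithful to the algorithm); an optional clamp
zeroes a negative branch and transfers the length to its sibling. Exactness
on additive matrices (topology and lengths to 1e-9) is property-tested, and
topologies are cross-checked against scikit-bio's independent NJ.

## Factorial correspondence analysis

Individuals are coded 0/1/2 copies per (locus, allele) column; missing loci
contribute zeros and thereby shrink the row mass, rather than being imputed
— the simplest defensible treatment and the one that keeps the row space
complete. The CA itself is the standard SVD of the standardized residuals
`(P − rcᵀ)/√(rcᵀ)`; eigenvalues are squared singular values, principal
coordinates are mass-scaled singular vectors, and the trivial (null) axes
are dropped at a relative threshold of 1e-10. Axis signs are fixed by
forcing the largest-magnitude row coordinate positive. Exact coordinates of
legacy desktop FCA implementations are not reproduced (their internal
coding is undocumented); the meaningful outputs are the eigenvalues —
verified against a dense eigendecomposition — and relative configurations.

## Admixture model

The sampler implements the no-linkage admixture model with uncorrelated
frequencies: flat Dirichlet(λ = 1) priors on cluster allele frequencies, a
symmetric Dirichlet(α) prior on individual ancestry with a single α shared
across clusters. α is sampled by default via a Metropolis step (Normal
proposal, SD = 0.05·α, uniform prior on (0, 10)); a fixed-α mode exists and
is what the tests use, since recovery checks want a fixed, weakly
informative α = 0.1. All four updates (origins z, ancestry Q, frequencies
P, α) are vectorized over individuals, loci and gene copies.

LnP(D) is the usual `mean − var/2` of the retained per-sweep complete-data
log-likelihood (sample variance, ddof = 1). Evanno's
`ΔK = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / SD(K)` requires ≥3 consecutive K and
≥2 replicates; it is NaN at boundary K and when the replicate SD is zero.

Chain lengths: the classic survey configuration (burn-in 50,000 / 100,000
retained) is available through the config, but the package defaults to
5,000 / 10,000, and the test and acceptance runs use 150–200 burn-in with
250–300 retained sweeps. On datasets of this size (≈100 individuals, ≈20
loci, strong or moderate structure) the chain mixes within tens of sweeps,
and these lengths already give stable label recovery and ΔK selection;
they are a deliberate desk-scale choice, not a recommendation for weaker
signals. Replicate seeds are derived from a base seed by fixed increments
and recorded in the manifest.

Cluster composition assigns each individual to its argmax-Q cluster (ties
to the lowest index, logged) and reports row-normalized percentages per
group, i.e. rows sum to 100. Reported summaries are invariant to cluster
relabeling; tests verify this by permuting cluster labels directly.

## Synthetic data generator

The generator emulates a small livestock diversity survey:

- **Drift**: multiallelic Balding–Nichols — ancestral frequencies p per
  locus from a flat Dirichlet, each of K source populations drawing its own
  frequencies from `Dirichlet(p(1−F)/F)`. F_ST is thus an explicit
  parameter; F = 0 short-circuits to identical frequencies.
- **Inbreeding**: with probability `target_fis` a genotype's second gene
  copy is an identical-by-descent copy of the first (origin drawn once),
  giving `E[F_IS] = target_fis` exactly. Heterozygote *excess*
  (F_IS < 0) cannot be generated by this device and is rejected.
- **Ancestry**: when the sampling groups correspond one-to-one with the K
  sources, each group draws purely from its own source (one-hot ancestry);
  this is what differentiation- and label-recovery fixtures need, since a
  group label must mean something for between-group θ to be recoverable.
  Otherwise individuals are ancestry-blind with `q ~ Dirichlet(α·1_K)` —
  the study-shaped case, where plumage phenotype does not track ancestry.
- **Missingness**: MCAR at a fixed per-genotype rate.

Presets: `togo-like` (94 individuals in 7 phenotype groups of sizes
5/19/19/8/5/18/20 plus a 35/59 zone split, 18 loci with per-locus allele
counts 2–25 averaging 6.0, F_ST = 0.012, F_IS = 0.17, α = 1.0, 2% missing),
`two-pop-differentiated` (2 × 50 at F_ST = 0.30, 20 loci),
`panmictic` (94 × 18, no structure), and `three-source-admixed`
(3 × 25 at F_ST = 0.15, 15 loci). The same seed yields byte-identical
matrices.

What the generator does **not** emulate: stepwise mutation (allele sizes
are exchangeable labels, not evolving repeat counts), linkage, null
alleles and allelic dropout (missingness is independent of genotype),
selection, and spatially structured gene flow. Passing tests therefore
demonstrate estimator correctness under the idealized model, not
robustness to genotyping artifacts such as null-allele-driven heterozygote
deficits. Note also that in the `togo-like` preset the phenotype and zone
labels are independent of ancestry by design, so realized between-group θ
is near zero even though the three sources differ at F_ST = 0.012.

## Numerical conventions and degenerate inputs

- Frequencies, Q rows and P rows are simplexes to 1e-9; Dirichlet draws are
  guarded against underflow with a 1e-300 floor before normalization.
- Monomorphic loci yield zero variance components and are excluded from
  multilocus sums with a warning; loci with zero denominators likewise.
- Empty (population, locus) cells are flagged, never silently averaged.
- Rarefaction below a cell's gene-copy count is undefined for that cell and
  skipped from averages with a warning.
- Display precision in pipeline outputs is 6 significant digits; the
  published-table transcriptions keep the original 3 (diversity) and 4
  (distance) decimals.

## Problem sizes used by the shipped checks

The acceptance script and test suite run entirely on simulated data at the
survey's own scale: 94 × 18 for the study-shaped analyses; 20 seeds of
2 × 50 × 20 loci for θ recovery; 20 seeds of 100 × 20 for F_IS recovery;
200 panmictic 94 × 18 datasets (199 permutations each) for the type-I error
of the deficit test; 100 random additive matrices (4–9 taxa) for NJ; and,
for the admixture stage, K = 2..5 with 5 replicate chains on 75 × 15
three-source data, repeated over 5 meta-replicates for the ΔK check.
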