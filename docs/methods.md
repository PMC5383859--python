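# Methods notes

These notes record the statistical models behind `chickpop`, the defaults
and why they hold their values, the numerical conventions, and the design
choices made where more than one reasonable construction existed.

## Genotype model

Genotype likelihoods L(reads | g), g ∈ {0, 1, 2} alternate-allele copies,
are the pipeline's input; they are stored max-normalized per triple (a
likelihood is defined only up to a constant) and a zero-depth triple is
the uninformative (1, 1, 1).

The calling model is a two-block Gibbs sampler per locus and group:

1. g_i | p ∝ L(reads_i | g) · HWE(g | p), HWE = ((1−p)², 2p(1−p), p²);
2. p | g ∼ Beta(1 + Σ alt alleles, 1 + Σ ref alleles) — a flat Beta(1, 1)
   prior on the group allele frequency.

Posterior summaries are plain averages over retained samples: per-genotype
posterior probabilities, the composite genotype E[g] ∈ [0, 2], and the
posterior-mean allele frequency per group × locus. The schedule defaults
to 10 000 steps, 6 000 burn-in, thinning to every 2nd step (2 000 retained
samples); "thinning every other step" is implemented as *retain* every 2nd.
Assumptions: Hardy–Weinberg within groups, no inbreeding, unrelated
individuals, biallelic sites, a single symmetric error rate.

**Prior grouping.** `fit_genotype_model` supports per-site and pooled
allele-frequency priors; the module default is per-site. The *pipeline*
default is pooled, a deliberate choice: per-site priors shrink every
low-coverage genotype toward its own site's mean, so the composite
genotypes carry site information injected by the prior rather than by
reads. On synthetic data (≈10 individuals/site, mean depth 6×) this
inflates the among-site φ from ≈0.04 (true genotypes) to ≈0.14 and makes
every downstream structure test fire. Using the site labels to build the
prior and then testing for site structure on the result is circular, so
the orchestrated analysis pools. Users studying a single population's
genotypes (not structure) may prefer per-site priors.

Mixing caveat: at a locus with no reads in the whole group, the frequency
chain is a slow random walk (lag-1 autocorrelation ≈ 1 − 1/n); the
prior-only limit (posterior ≈ (⅓, ⅓, ⅓), composite ≈ 1) emerges only on
long chains. The test suite uses a 30 000-step chain for that check.

**Certainty mask.** Downstream hierarchical variance analysis keeps only
composites within 0.1 of 0, 1 or 2 (boundary inclusive, with a 1e-12
floating-point guard); others are missing data.

## Filters

Order: presence/MAF → one SNP per contig → depth windows → genotype model.
Presence requires ≥ 90% of individuals with ≥ 1 read. The naive allele
frequency behind the MAF rule is the likelihood-weighted expected genotype
summed over covered individuals, p̂ = Σ E[g]/(2 n_obs); retain iff
MAF ≥ 0.05. Depth windows use *mean* depth (per locus across individuals:
[4, 15]×; then per individual across retained loci: [3, 10]×), inclusive at
both ends; mean is the conventional aggregation for GBS coverage summaries
and the boundaries are kept inclusive so the printed window values are
themselves retained. Each removed locus is attributed to the first rule
that removed it, so the removal log reconciles exactly with the input.

## Differentiation

Hudson's estimator with finite-sample corrections, combined genome-wide as
the ratio of averages Σ numerators / Σ denominators (the stable way to
aggregate a method-of-moments ratio estimator; the average of ratios is a
different, noisier statistic, and a regression test pins the choice).
Negative estimates are retained: the pairwise permutation test is
two-sided. Loci monomorphic for the same allele in both samples are
skipped per pair. Allele frequencies come from composite genotypes
(p̂ = mean composite / 2, allele count 2N); the null permutes individuals'
site labels preserving group sizes, and the 95% bounds are empirical
2.5/97.5 percentiles of the permuted statistics (at the default 100
permutations those percentiles are interpolated from few draws and the
interval's nominal two-sided level is ≈7%, approaching 5% as permutations
grow; the type-I calibration check therefore measures at 499).

Nei's D uses the normalized identity of biallelic frequency vectors and
returns +∞ for disjoint fixed alleles.

## Structure

PCA is an SVD of the column-centered, unscaled composite matrix. PERMANOVA
on the first two ordination axes uses the standard distance-based pseudo-F
with free label permutation and the (1 + exceedances)/(1 + permutations)
p-value convention. Note a small-design floor: with two groups of five,
random permutations recreate the observed partition with probability
2/C(10,5) ≈ 0.8%, so p-values below ≈0.01 are unreachable there.

DAPC is k-means over PCA scores (10 restarts, 300-iteration cap) scored by
BIC = N ln(WSS/N) + k ln(N), then linear discriminant analysis on the
retained PCs with Gaussian assignment probabilities. The BIC formula only
penalizes effectively when the clustered space has enough dimensions: in
one or two dimensions k-means shrinks WSS faster than ln N for *any*
Gaussian data and the criterion always picks k_max. The pipeline therefore
searches clusters over many PCs (default 60, a near-lossless transform of
the data, mirroring how adegenet's find.clusters transforms with a large
n.pca before k-means) while retaining 1 PC only for the discriminant step.
The discriminant solver is SVD-based, which implicitly rank-truncates a
singular within-cluster covariance.

## Hierarchy (AMOVA)

Squared Euclidean distances between composite-genotype vectors, computed
pairwise-complete over each pair's shared non-missing loci and rescaled by
L/L_shared (unbiased under missingness independent of genotype). Sums of
squares follow the distance-based identity (within-stratum pair sums over
stratum size); variance components use the nested moment equations with
unequal-sample-size coefficients; φ_CT, φ_SC, φ_ST follow their standard
identities. Negative components are reported with a flag, not truncated —
truncation would bias the percentage partition. Individuals are the lowest
unit (composites are continuous, so no within-individual allele level).
Permutation schemes per level: φ_ST — individuals across all sites;
φ_SC — individuals among sites within their transect; φ_CT — whole sites
among transects. With six sites there are only 15 distinct site-to-transect
arrangements, so p_CT cannot fall below ≈1/15.

## Space

Haversine distances with mean Earth radius 6 371.0 km; elevational distance
is |Δ elevation| in meters. MRM regresses the unfolded lower triangle of
the response on the predictors by OLS; inference permutes the response
matrix's rows and columns *jointly* (permuted responses remain valid
distance-matrix unfoldings — required for Mantel-type validity), with R²
for the overall test and |coefficient| for per-predictor two-sided tests.
The headline response is Nei's D, with genome-wide F_ST also emitted.

## Parallel divergence

Per-transect high-vs-low locus F_ST from composite frequencies; the
outlier threshold per contrast is the empirical quantile with linear
interpolation between order statistics (rank 1 + (L−1)q) over that
contrast's defined loci, membership strictly above. Sharing counts are
exactly-2 and exactly-3 (the closed form for exactly-2 reproduces the
reported expectations; the ≥2 form does not). The permutation null draws
three independent uniform subsets of the observed sizes per replicate
(equivalent to permuting locus labels within each contrast), 10 000 times,
reporting means, count-distribution 95% percentiles, and Monte-Carlo
standard errors; the closed form is the independent oracle the permutation
engine is tested against. L for the null is the count of loci defined in
all three contrasts.

## Synthetic data

The generator reproduces the study *design*: 6 sites = 3 transects ×
{high, low}; Balding–Nichols site frequencies (Beta with mean p and
variance F·p(1−p); pairwise Hudson F_ST ≈ F); HWE genotypes;
negative-binomial depths (mean 6×, dispersion 2 — inside the study's
3–10× per-individual window with GBS-like overdispersion); binomial read
errors at ε = 0.01; ancestral frequencies uniform on (0.05, 0.95) mimicking
an upstream MAF filter. `fst_total` defaults to 0.02, the study's reported
genome-wide mean. Optional outlier loci shift high sites by +δ and low
sites by −δ (δ = 0.3 by default), making divergence parallel across
transects by construction. Not emulated: linkage disequilibrium, selection
dynamics, relatedness/inbreeding, base-quality variation, and contig
dropout beyond depth 0.

**What passing tests do and do not show.** Two properties of the synthetic
world differ from the study's real data and matter for interpretation:

- A *true* drift parameter of F = 0.02 is genuinely detectable structure
  at any desk scale (detection roughly requires F·√(N·L) < 1 to fail, i.e.
  fewer than ~50 loci at N = 60). On synthetic data the among-site tests
  (PERMANOVA on sites, AMOVA φ_SC) therefore correctly reject, and the
  individual-level φ_ST sits near its construction value 2F/(1+2F) ≈ 0.04.
  The study's own data behaved differently — its pairwise permutation
  *nulls* nearly equal its observed F_ST values, the pattern expected when
  true differentiation is ≈ 0 and the printed F_ST mostly reflects
  low-coverage estimation noise. The groupings that are exchangeable by
  construction (elevation classes, site-to-transect assignment, DAPC
  cluster/site alignment) do reproduce the study's null findings.
- Composite-genotype F_ST at low coverage is biased: pooled-prior
  shrinkage attenuates between-site frequency differences (estimates near
  0 at mean depth 6×), while per-site priors inflate them. The
  permutation null carries the same distortion, so the *verdicts* stay
  calibrated (verified by type-I simulation), but the point estimates from
  the full low-coverage pipeline are not comparable to estimates from true
  genotypes. Shrinkage also correlates the three contrasts' locus F_ST
  values through shared locus information content, which can push observed
  shared-outlier counts above the independent-subset null even without any
  divergent loci — a caveat that applies equally to the real analysis this
  package reimplements.

## Determinism and problem sizes

Every stage takes an explicit seed; the pipeline derives per-stage seeds
from a master seed by SHA-256 over (seed, stage name), so stages re-run
independently and bundles reproduce byte-identically (manifest timings
aside). The test suite and the acceptance script run the heavier
simulations at reduced sizes chosen to keep each statistical check's
Monte-Carlo error well inside its asserted tolerance: genotype-model
recovery at 500 loci × 150 individuals, estimator-recovery checks at
5 000 loci, type-I calibration at 500 replicates, the pipeline regime run
at 1 000 loci × 60 individuals, and the shared-outlier nulls at the full
published scale of 18 073 loci (they cost only seconds).

## Known limitations

- No Weir–Cockerham estimator, no bootstrap CIs over loci, no haplotype
  (allele-level) AMOVA, no admixture/Bayesian clustering, no a-score
  optimization for the number of retained discriminant PCs.
- The flat Beta(1, 1) frequency prior is the minimal hierarchical
  structure; no hyperprior across loci.
- VCF support is a read-only subset (biallelic records with GL or PL and
  per-sample depth).
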