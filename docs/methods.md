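# Methods

## Model

The social mixed model treats each focal individual's phenotype as the
sum of fixed covariate effects, its own additive polygenic effect (DGE),
the summed polygenic social effects of its cage mates (IGE), matching
direct and social environmental effects, and a cage effect:

    y_f = X_f b + a_D,f + e_D,f + Z_f a_S + Z_f e_S + W_f c

* (a_D, a_S) are jointly Gaussian with covariance blocks σ²_AD·A,
  σ_ADS·A, σ²_AS·A, where A is the genetic relatedness matrix;
* (e_D, e_S) are iid across individuals with an unstructured 2×2
  covariance (σ²_ED, σ_EDS, σ²_ES);
* c ~ N(0, σ²_C I) is shared by cage members;
* Z is the cage-mate indicator (zero diagonal), W the cage indicator;
  for complete cages Z = W W' − I.

Assumptions: additivity of social effects across cage mates (an
"additive" aggregation; the generator can also produce "averaged" social
effects for power comparisons), Gaussian phenotypes after normalization,
complete and stable cages, and a polygenic architecture captured by the
GRM kernel.

The GRM is the cross-product of column-standardized dosages divided by
the variant count, so its diagonal averages ≈ 1 and variance components
are comparable across panels. Standardization implies A·1 = 0 exactly; see
"Estimation" for the consequence.

With equal cage sizes s, the three non-genetic components are not
separately identifiable; the environmental covariance collapses to a
diagonal σ²_E and a within-cage covariance ρ_E σ²_E with

    σ²_E = σ²_ED + (s−1) σ²_ES + σ²_C
    ρ_E σ²_E = 2 σ_EDS + (s−2) σ²_ES + σ²_C

The two parameterizations span the same covariance set (the collapsed
PSD boundary ρ_E = −1/(s−1) is attained by the full form at
σ_ES = σ_ED/(s−1), σ_EDS = −σ_ED σ_ES, σ²_C = 0), so their maximized
likelihoods and genetic estimates agree; the test suite verifies this to
1e−3 on simulated data. The collapsed form is the default whenever all
cages share one size; it refuses unequal sizes.

## Estimation

Variance parameters are estimated by REML, maximized by L-BFGS with
analytic gradients. Two numerical points matter:

* **Why REML.** Because A·1 = 0, the genetic components contribute no
  variance along the constant vector; if X contains an intercept, the
  b-profiled ML likelihood diverges (≈ −½ log λ) as the environmental
  cage-mean eigenvalue λ → 0, where C becomes singular exactly inside
  span(X). Optimizers chase this divergence into numerically chaotic
  territory. REML excludes the fixed-effect directions and is bounded.
  All likelihood-ratio tests compare models with identical fixed
  effects, and the genome scans never refit variance components, so
  nothing downstream needed the ML criterion. `method="ml"` remains
  available.
* **Contrast-basis evaluation.** REML is computed in an orthonormal
  basis K of span(X)-perp as −½[(n−k)log 2π + log|K'CK| + y'K(K'CK)⁻¹K'y],
  not as log|C| + log|X'C⁻¹X|: near the boundary the latter is a
  difference of two diverging terms and cancels catastrophically,
  whereas K'CK stays well-conditioned.

Positive-definiteness is enforced by parameterization rather than
constraints: the genetic and full environmental 2×2 blocks through their
Cholesky factors, the cage variance through its square root, and the
collapsed environmental block through the square roots of its two
eigenvalue channels (cage means: σ²_E(1+(s−1)ρ_E); within-cage
contrasts: σ²_E(1−ρ_E)), which makes the ρ_E = −1/(s−1) boundary smoothly
reachable. Boundary estimates (a variance fitted at zero) are valid
outputs; ρ is reported as undefined when either genetic variance is below
1e−10.

Optimization starts from a deterministic moment-based split of the OLS
residual variance plus (by default) one seeded random restart; the full
environmental model additionally warm-starts from the collapsed optimum
mapped back into the full parameterization, which handles the full
form's flat ridge. Convergence: L-BFGS-B with ftol 1e−13, gtol 1e−7,
maxiter 800. A fitted C can be singular on the boundary; the reported GLS
fixed effects use the identity that the estimator is invariant to adding
X D X' to C, which restores definiteness without moving b̂, and
downstream consumers factor C through an escalating-jitter Cholesky.

Aggregate contributions are sampleVar(σ²_AD A)/sampleVar(C) and
sampleVar(σ²_AS Z A Z')/sampleVar(C) with
sampleVar(M) = Tr(PMP)/(n−1) = (Tr(M) − ΣM/n)/(n−1). Aggregate IGE is
tested by a 2-df LLR against the fit with σ²_AS = σ_ADS = 0 (conservative:
the null pins a variance to the boundary); ρ by 1-df LLRs against ρ = 0
(σ_ADS = 0, diagonal genetic Cholesky) and |ρ| = 1 (rank-one genetic
block v v', which profiles the sign of σ_ADS through the signs of v — the
better-likelihood sign wins; conservative). An LLR statistic more
negative than −1e−3 raises an optimization-failure error; smaller
deficits are optimizer noise at a shared optimum and truncate to zero.
Per-phenotype q-values for the aggregate IGE tests use Storey's method
(π₀ by the cubic smoother, falling back to π₀ = 1 for short p-vectors).

## Genome scans

The covariance C is estimated once per phenotype in the no-locus model
and held fixed. Each variant's models are then pure fixed-effect
comparisons by GLS after Cholesky whitening, with a global scale on C
profiled, giving LLR = n·log(RSS_null/RSS_alt) and χ²(1) p-values:

* igeGWAS: [X, G] versus [X, G, ZG] — the direct genotype G is the
  conditioning covariate;
* dgeGWAS: [X, ZG] versus [X, ZG, G].

Conditioning is what keeps igeGWAS calibrated when every individual is
both focal and partner: within a complete cage ZG = (cage total) − G, so
after the cage-correlated covariance down-weights between-cage contrasts,
an unconditioned social test is in large part a test of −G and inherits
any direct effect of the variant. The calibration experiment reproduces
this: the conditioned scan's null p-values are uniform while the
unconditioned test at a variant with a 20%-variance direct effect rejects
at ~270× the nominal 0.001 rate.

Social genotypes use the cage-mate **sum** coding; the **average** coding
is exposed because it rescales b_S by the number of cage mates while
leaving p-values unchanged — bit-identical, in fact, since the per-variant
algebra is written in closed-form dot products and halving a column
rescales every intermediate by exact powers of two. Variants with MAF
below 0.01 (configurable) are skipped; a tested vector with zero variance
yields a flagged row with p = 1. Individuals missing the phenotype drop
out as focal rows but keep contributing as partners (social genotypes are
computed over the full panel before focal subsetting, and the focal
covariance is the corresponding submatrix of C).

## Permutation FDR

Each of K (default 100) permutations applies one seeded row permutation
to the whole tested-genotype matrix — social matrix for igeGWAS, direct
for dgeGWAS — leaving y, X, the GRM, C and the conditioning matrix
untouched, then reruns the scan. Loci are formed by greedy clumping: the
best remaining variant leads a locus and claims a ±window/2 interval
(window 1.5 Mb, reusing the population's association confidence-interval
width; ties broken by chromosome then position). For each observed lead
p-value x,

    FDR(x) = #{permuted loci with P ≤ x} / (K · #{observed loci with P ≤ x})

made monotone by a running minimum over decreasing x; calls are reported
at FDR < 10%. Counting raw variants instead of clumped loci is available
(`count_unit="variant"`); locus counting is the default.

## Post-GWAS

At a significant locus the 1.5-Mb window around the lead is re-scanned
with the dense (unpruned) variant set using the same engine and
conditioning. The association plateau is the contiguous run of variants
within 1.5 −log10 P units of the lead, extended greedily from it — a
deterministic proxy for what locus-zoom plots show. Candidate causal
genes are genes overlapping the plateau ± a 100-kb proximity margin whose
symbol does not start with Gm, Rik, Mir, Fam, or Tmem (the exclusion list
is configurable; the prefix rule is applied literally, including to
"Rik", which in MGI nomenclature usually appears as a suffix). Variance
explained by lead variants comes from a refit with fixed effects for the
direct and social genotypes of all leads:

    var(ZG_j b̂_S,j) / [Σ_c var(X_c b̂_c) + Σ var(G b̂_D) + Σ var(ZG b̂_S) + sampleVar(C)]

(direct analogue for DGE loci), where var(·) is the sample variance of
the fitted effect vector, so the listed fractions plus the residual
fraction sum to one by construction.

## Synthetic data

The generator emulates the study design, not its genomes: biallelic
dosages are drawn Binomial(2, f) independently per variant (no LD, no
population structure, no imputation noise), f uniform within a MAF class
(low < 0.05, medium 0.225–0.275, high > 0.45) or range; cages are random
same-size partitions (size 3 by default); relatedness can be injected by
duplicating individuals with a 5% per-variant resampling rate. Default
variance targets are the recovery recipe: DGE 15%, IGE 20%, ρ_A = 0.47,
DEE 22%, IEE 16%, ρ_E = −0.97, cage 26% — with raw coefficients rescaled
by each component's sampleVar so a target is exactly that component's
share of sampleVar(C), and "realised" fractions reported as
target/sampleVar(total). Polygenic draws use the exact dosage factor
(Xs/√p) u so their covariance is exactly σ²·A. Because the genomes are
LD-free, passing tests demonstrate the statistical machinery — they say
nothing about LD-induced clumping behaviour or fine-mapping resolution on
real genomes.

Local fixed effects support three generative modes — direct (G·β),
additive social (ZG·β), averaged social ((Z/N)·G·β with N = cage_size − 1,
the number of cage mates) — and three effect scales: raw dosage (default),
per-standardized-allele, or fraction-of-variance. Raw-dosage coding is the
default because it is what makes power depend on MAF at fixed allelic
effect, the behaviour the power experiment measures.

## Experiments and problem sizes

All experiment sizes are chosen to run comfortably on one CPU and are
fixed in the code:

* **Likelihood oracle**: n = 30 (10 cages), 25 random parameter points
  against a dense multivariate-normal log-density, tolerance 1e−8.
* **Environmental equivalence**: 8 datasets at n = 150; maximized
  restricted likelihoods within 1e−3, genetic parameters within 1e−2.
* **Aggregate-IGE recovery**: n = 900, one fixed panel of 400 variants,
  target IGE ∈ {0, 0.1, 0.2, 0.357}, 20 replicates per point; estimates
  compared with realised values (2 MC SE at interior points; at truth 0
  the non-negative estimator's half-normal boundary bias is checked to
  stay under 2% of phenotypic variance), regression slope required in
  [0.9, 1.1].
* **Calibration**: n = 600, a 2000-variant panel, null-IGE phenotypes
  with a 20%-variance local DGE on the high-polygenic recipe (σ² values
  20/20/30/30/25, ρ_A = 0.5, ρ_E = −0.97). The genome-wide null scans
  re-estimate C from each replicate's phenotype — using the bare
  generative covariance would leave the causal variant's variance
  unmodeled and visibly deflate every other test at KS resolution — while
  the tests at the causal variant use the generative covariance (with
  conditioning, the local direct effect is part of that model).
  Uniformity is assessed by KS on a single replicate's scan: pooling
  replicates that share a phenotype draw would overstate the KS evidence.
* **Power**: recipe σ² values 17/17/19/15/25, ρ_A = 0.65, ρ_E = −0.8;
  n = 900, allelic effect 0.2 on the raw-dosage scale, threshold
  −log10 P = 5, 200 replicates per mode × MAF class, each replicate
  drawing a fresh causal variant and phenotype against a fixed panel
  covariance. Expected ordering at cage size 3: additive IGE > DGE >
  averaged IGE.
* **FDR validity**: 12 synthetic genomes (8 in the acceptance script),
  n = 600, 500 variants spaced ≥ 3 Mb apart, 10 causal social-effect
  variants at 3% of variance each, K = 20 permutations; realized FDP
  among FDR < 10% calls required ≤ 0.20.

The experiment fast paths share their per-variant algebra with the scan
engine through closed-form whitened dot products; a test pins the two
paths together to 1e−9.

## Known limitations

* Synthetic genotypes carry no LD: clump windows on simulated genomes
  almost always hold a single variant, so locus-level and variant-level
  FDR counting coincide there.
* The collapsed environmental model requires equal cage sizes; unequal
  sizes force the full form, whose extra parameters are then only weakly
  identified at small n.
* The χ²(1) approximation to n·log(RSS₀/RSS₁) is slightly conservative at
  small n; at the cohort sizes used here the effect is not detectable at
  2000-variant KS resolution.
* The sibling screen is a fixed GRM threshold (default 0.3), a proxy for
  visual outlier inspection; the appropriate value depends on the
  population's background relatedness.
* Multi-trait models, X-chromosome dosage compensation, and LD-aware
  calibration are out of scope.
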