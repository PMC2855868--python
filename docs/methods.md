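# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want to
know.

## Per-trait strain/sex model

Each trait is analyzed under the two-way layout

    y_ijk = mu + strain_i + sex_j + (strain x sex)_ij + e_ijk.

Hypothesis tests are marginal ("Type III") F tests: the full model is fit
with sum-to-zero coding and each effect is tested by deleting its columns
and comparing residual sums of squares, so the tests do not depend on term
order even for unbalanced cells. Degrees of freedom come from matrix ranks,
which keeps the tests defined when cells are empty (a trait measured in one
sex loses its sex and interaction tests but keeps the strain test). A trait
with zero residual and effect variation is flagged degenerate and reported
with p = 1 rather than NaN so downstream FDR machinery is unaffected.

Variance components treat all model effects as random (the convention of
classical variance-component software). Two estimators are provided:

* **REML** (default). The one-factor model is profiled analytically per
  strain block and the variance ratio optimized in 1-D, then polished on
  the analytic score equation with a bracketed root-finder; this reaches
  machine precision, so balanced designs reproduce the ANOVA estimators
  exactly. The three-component pooled model (strain, sex, strain x sex)
  profiles the error variance out and optimizes the log variance ratios
  with L-BFGS-B through a Woodbury factorization, so the cost scales with
  the number of random-effect levels (~3s + 2), not the number of animals.
  Three starting points guard against local optima.
* **ANOVA** (expected mean squares). Exact for balanced data; unbalanced
  two-way designs use the harmonic-mean cell size, a documented
  approximation retained mainly as an independent cross-check on REML.

Negative estimates are truncated at zero and the truncation recorded.
Because variance-component estimates are biased under non-normality, the
residual skewness and kurtosis are attached to every estimate as
diagnostics rather than attempting a correction.

Heritability is the strain intra-class correlation
h² = σ²_strain/(σ²_strain + σ²_error). For the pooled scope the model
includes sex and interaction components by default (`include_sex_terms`
switches to the strain-only model); the per-sex scopes use the one-way
model on that sex. The standard error is the classical large-sample ICC
variance

    Var(t) = 2 (1-t)² [1 + (n0-1) t]² / [n0 (n0-1)(s-1)],

with Searle's effective per-strain size n0 = (N − Σn_i²/N)/(s−1) absorbing
unbalanced group sizes. This is one defensible reading of "adjusted for
unbalanced data"; the formula is isolated in one function so an alternative
can be swapped in.

Partial ω² for an effect is σ²_effect divided by the sum of all four
components. Effect classes use the conventional cuts: large ω² > 0.30,
intermediate 0.10 < ω² ≤ 0.30, small ω² ≤ 0.10 (ties resolve downward,
matching the strict inequality that defines the small class).

**Sex policy.** A trait is mapped separately by sex when its sex or
interaction q-value falls below 0.05 ("trend toward a sex difference"
operationalized at the same FDR level used everywhere else); otherwise the
sexes pool. Pooled strain means are least-squares means — the equal-weight
average of the two per-sex strain means — so unbalanced sex counts do not
tilt the strain mean; a strain missing one sex gets a missing pooled cell.

**q-values.** Storey's procedure with π̂₀ estimated on a λ grid
(0.05–0.95), smoothed by a cubic polynomial and read off at the largest λ,
clipped to (0, 1]; with fewer than 100 tests π̂₀ is fixed at 1, making the
result exactly Benjamini–Hochberg (also the π₀ = 1 behavior, which the
tests verify against statsmodels).

**Univariate outliers** are values more than 5 SD from the trait mean
(strict inequality). They are flagged for quality assurance only and
retained in every analysis.

## Sub-population contrast

Old and new RI sub-populations are compared with the nested model
y = mu + subpop + strain(subpop) + e and the alternate ratio
F = MS_subpop / MS_strain(subpop) on (g−1, s−g) degrees of freedom: mice
are replicates within a strain, so strain is the error stratum, and using
the mouse-level error term would badly inflate type-I error whenever
strain effects exist (the test suite demonstrates both the calibration of
the nested test and the inflation of the naive one). Sums of squares are
computed on strain means weighted by per-strain animal counts; an
unweighted variant is a flag away, since the right weighting for
unbalanced data is genuinely ambiguous. Zero within-group strain variance
with differing group means is flagged degenerate rather than reported as
an infinite F.

## QTL mapping

Scans regress strain means on the expected D-allele dosage, LOD =
(n/2)·log₁₀(RSS₀/RSS₁), equivalently −(n/2)·log₁₀(1−r²), computed as one
matrix product per scan. Between typed markers the dosage conditions on the
flanking RI genotypes: the inbred RI chromosome is modeled as a Markov
chain whose step probabilities are meiotic Haldane fractions expanded by
R = 4r/(1+6r) (sib-mating RI accumulation), giving
P(D | L, R) = t₁(L,D)t₂(D,R) / Σ_x t₁(L,x)t₂(x,R). This matches the
generator's transmission model exactly, so pseudomarker dosages are
consistent with the simulated linkage.

Defaults: 1-cM pseudomarker grid (the grid a practitioner would pick for
an RI panel of this density; thresholds by default use typed markers only,
where the max-LOD distribution is essentially identical and the null scans
vectorize); strains dropped per-scan on missing data (complete case, the
strain-mean workflow); permutation unit is the strain (means permuted
against genotype rows, preserving marker correlation); suggestive and
significant thresholds are the 37th and 95th percentiles of the null
genome-wide max LOD — genome-wide adjusted P < 0.63 (= 1 − e⁻¹, one
expected false positive per scan) and P < 0.05. Support intervals are
one-LOD drop-offs with linear interpolation between grid points, truncated
at chromosome ends; cM→Mb conversion interpolates linearly between typed
markers. Peak ties report the leftmost position with all co-peaks listed.
Positional candidates are genes whose half-open [start, end) interval
overlaps the support interval at all.

Group-conditional allele means (`marker_effect_by_group`) summarize a
marker's effect within each sub-population, the construction used to
detect alleles whose effect reverses sign between sub-populations and
thereby vanishes in the combined panel.

## Expression correlates

Genetic correlation is the Pearson correlation of strain means over shared
strains (Spearman available), p from the t transform on n−2 df. Correlate
lists keep probes with raw p < 0.001 — deliberately uncorrected, since the
lists feed a convergence analysis rather than a hypothesis test — and
collapse probes to genes keeping the max-|r| probe.

## Factor pipeline

The strain-by-trait matrix has more traits than strains, so the sample
correlation matrix is singular. The chain is: drop strains missing > 25%
of traits (strict inequality); column-mean imputation (valid under
missing-at-random; it leaves column means unchanged, so standardization
order matters only through variances); standardize; Schäfer–Strimmer
shrinkage toward the identity correlation with the analytic intensity
λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij², clipped to [0, 1] — positive
definite whenever λ* > 0; unrotated maximum-likelihood factor analysis by
EM on the shrunk matrix (SMC-based start ψ₀ = 1/diag(R⁻¹), convergence at
log-likelihood gain < 1e-8 or 2000 iterations, uniquenesses floored at
1e-3 with floored traits flagged as Heywood cases). Because the likelihood
identifies Λ only up to orthogonal rotation, the canonical constraint
Λ'Ψ⁻¹Λ diagonal is imposed after convergence — this *is* the classical
"unrotated" ML solution; no varimax/oblimin rotation is ever applied.
Factors are ordered by variance explained (column sums of squared loadings
over p) and each column's sign is fixed so its largest-|loading| entry is
positive, which stabilizes outputs across platforms. Note that factors of
equal strength are rotationally degenerate even under the canonical
constraint: per-factor recovery is only meaningful when the simulated
factors differ in strength, which the recovery simulations therefore
arrange (blocks of 15/10/5 traits with loadings 0.9/0.8/0.7).

Factor counts are reported from two eigenvalue criteria on the *sample*
correlation: parallel analysis against the 95th-centile eigenvalues of
seed-fixed random normal data (100 draws; the mean reference is available
but fails to control spurious factors on null data), and optimal
coordinates — retain while the eigenvalue exceeds both the linear
extrapolation through the next and last eigenvalues and the parallel
reference. The fitted k is an explicit argument everywhere; nothing is
chosen silently.

Scores are regression (Thomson) scores F = Z·R⁻¹·Λ̂ using the shrunk R
(the raw matrix is singular for n < p). Factors below a 1.3% variance
floor are flagged excluded from interpretation output. Scores feed the QTL
scanner as ordinary strain means. `FactorAnalysisPipeline` wraps the chain
as a scikit-learn transformer (fit learns strains/means/SDs/correlation/
model; transform scores new strains on the fitted scale).

## Multivariate outliers

D² = (x−x̄)'S⁻¹(x−x̄) over complete-case strains with p from the upper
χ²(#traits) tail; strains with p < 0.05 are flagged. Mean and covariance
include the candidate strain by default (simplest convention; a
leave-one-out variant is provided and is strictly more sensitive to true
extremes). A singular covariance falls back to the shrinkage correlation
rescaled to covariance. Per-trait standing (high/intermediate/low) uses
panel tertiles — an interpretation, since no formal definition of the
labels exists. The χ² criterion is asymptotic: at n = 200 strains the null
flag rate is ~0.047 at α = 0.05, and smaller panels are mildly
conservative.

## Bipartite integration

Each candidate or correlate list is a phenotype vertex; genes link to the
lists containing them (edges deduplicated). Genes rank by degree, ties
broken by id for determinism; the top slice is ceil(fraction·n_genes) with
ties at the cut admitted only up to the slice size. A `min_degree=2`
filter (off by default) removes singleton genes that carry no convergent
evidence. Over-representation is the one-sided hypergeometric tail
P(X ≥ k) against the full annotation universe, with an optional BH column;
the universe choice is configurable because enrichment is sensitive to it.

## Synthetic data generator

Genotypes: each chromosome of each strain is an independent two-state
Markov chain with stationary probabilities ½/½ and adjacent-marker flip
probability R = 4r/(1+6r) from the Haldane r for the map step. This
reproduces the expected pairwise statistics of a sib-mated RI panel
without simulating the breeding pedigree; it does *not* reproduce
higher-order haplotype sharing among strains, the advanced-intercross map
expansion of the newer lines, residual heterozygosity, or genotyping
error (H/U calls are supported by the readers but not emitted). A small
set of private loci is fixed for B in the older sub-population while
segregating in the newer one.

Phenotypes: y = mu + Σ a·g + u_strain + s_sex + (us) + e with components
drawn to realize configured variance fractions (total non-QTL variance 1).
The sex contrast is ±sqrt(v/2) so that the two-level variance *component*
(Σ(effect−mean)²/(levels−1) = 2δ²) equals the configured fraction — the
scale on which ANOVA/REML and ω² operate. Defaults emulate the surveyed
panel design: 32 + 37 strains in two sub-populations, 3–11 mice per sex
per strain (one draw per strain, sexes equal), 20 chromosomes × 50 markers
over 100 cM (1 Mb/cM), ~250 traits with strain fractions spanning
0.05–0.7 across ten named batteries, and missing-at-random entries on
request. Not emulated: litter and site covariates, battery-order effects,
non-normal trait scales, epistasis, and genotype-missingness patterns —
so passing tests certify the estimators and their calibration under the
model, not robustness to those real-data features.

Expression: probes are Gaussian noise except configured cis probes, which
add γ·g at a marker, so expression–trait genetic correlation can be
planted and null calibration checked at scale. Gene annotations tile the
genome in non-overlapping 1-Mb half-open intervals; gene sets sample the
annotation reproducibly by seed.

## Problem sizes and numerics

Calibration and recovery studies run at sizes chosen to make Monte-Carlo
error small relative to the assertion bands while staying desk-scale:
heritability recovery at 60 strains × 8/sex × 200 replicates per level;
type-I calibration at 400 replicates; permutation calibration at 200 null
traits × 500 permutations on a 20 × 50 genome (the threshold estimate from
500 permutations is interchangeable with 1000 for calibration purposes);
factor recovery at n = 200, p = 30. Tolerance choices: REML score-equation
polish to 1e-14 in the log ratio; EM tolerance 1e-8; shrinkage and LOD
oracles asserted to 1e-10. All generators and analyses are deterministic
given a seed; the pipeline writes a config-hash + seed header on every
output file and a manifest of every threshold used.

## Known limitations

* Single-QTL scans only: no composite-interval mapping, multiple-QTL
  models, or epistasis scans.
* The 25%-missingness filter and column-mean imputation assume
  missing-at-random; informative missingness biases the factor stage.
* REML assumes Gaussian components; the skewness/kurtosis diagnostics
  warn but do not correct.
* Mahalanobis flagging uses the asymptotic χ² criterion, slightly
  conservative at small n; no robust (MCD) covariance option yet.
* Connectivity ranking is biased toward phenotypes measured in many
  assays; collapsing phenotype vertices by trait family before degree
  counting would mitigate this and is left as an extension.
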