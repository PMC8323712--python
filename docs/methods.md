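# Methods

This note documents the statistical models implemented in `lipomr`, the
assumptions behind them, the synthetic-data conditions under which the
package is validated, and the numerical and design choices that were
genuinely open.

## Two-sample summary-data MR

All estimators operate on a harmonized panel: J variants with exposure
associations βˣ (J×K, SD units per effect-allele copy), outcome
associations βʸ (J, log-odds for binary outcomes) and standard errors,
expressed on a common effect allele per variant. The identifying
assumptions are the usual instrumental-variable ones: instruments are
associated with the exposure, independent of confounders, and affect the
outcome only through the exposure (no horizontal pleiotropy, except as
modelled by MR-Egger's intercept).

**IVW as GLS.** The causal effect is the generalized weighted
least-squares slope of βʸ on βˣ through the origin with weight matrix
Ω⁻¹, Ω = D·R·D, D = diag(seʸ), R the instrument LD correlation. With
R = I this is algebraically the classical inverse-variance weighted
estimator Σ(βˣβʸ/seʸ²)/Σ(βˣ²/seʸ²); with correlated cis instruments
(gene-region analyses) R comes from a reference panel. The fixed-effects
SE is sqrt((βˣᵀΩ⁻¹βˣ)⁻¹); the random-effects SE multiplies it by
max(1, sqrt(Q/dof)) where Q is the GLS residual chi-square under the
fixed-effects fit — a multiplicative overdispersion model bounded below so
random-effects SEs never undercut fixed-effects ones. p-values use the
normal distribution throughout (summary-data MR convention; J is
moderate). Q and J are always reported so heterogeneity is auditable.

**MR-Egger.** Before fitting, each variant's row is oriented so βˣ ≥ 0
(signs flip jointly across all traits and the outcome; the LD matrix is
conjugated by the same sign vector). This is the standard convention that
makes the intercept interpretable as average directional pleiotropy. The
slope is the causal estimate under the InSIDE assumption;
random-effects scaling uses J−2 degrees of freedom. A design in which all
oriented βˣ are equal is collinear with the intercept and rejected. Note a
consequence of orientation: "constant pleiotropy" is constant on the
oriented scale, so validation fixtures that inject a constant c into βʸ
generate panels with βˣ ≥ 0 already; on such panels adding c shifts the
intercept by exactly c and leaves the slope exactly unchanged (a linear
identity, since the weights do not depend on βʸ).

**Multivariable MR** regresses βʸ on all K exposure columns jointly
(direct effects, each conditional on the others), requiring J > K and a
full-rank design; exposure pairs with |r| > 0.999 are reported as
collinear. An all-zero exposure column yields a zero estimate flagged with
infinite variance rather than an error, so pipelines degrade gracefully.

## MR-BMA

The model-averaging stage works on the IVW-standardized system
ỹⱼ = βʸⱼ/seʸⱼ, X̃ⱼₖ = βˣⱼₖ/seʸⱼ with each column of X̃ scaled to unit
Euclidean norm (scale factors retained to back-transform effects to
per-SD units). For an exposure subset S the working model is

    ỹ = X̃_S θ_S + ε,  ε ~ N(0, I),  θ_S ~ N(0, σ² I),

whose marginal likelihood is Gaussian and closed-form; it is evaluated via
the Woodbury identity on the |S|×|S| Gram matrix for speed and includes
the −(J/2)·log 2π constant (irrelevant to posteriors, but it lets the
implementation be checked against direct numerical quadrature in absolute
terms). Defaults σ = 0.5 and prior inclusion probability 0.1 follow the
established calibration of this method family; both are exposed in
`BMAConfig`. All non-empty subsets up to `max_model_size` are enumerated
exhaustively (practical for K ≤ 20; the studies this package emulates have
K = 5 or 10). The null model is excluded from enumeration: the method
ranks causal candidates, and excluding it rescales every model posterior
equally, leaving MIP *ordering* unchanged. MIPₖ sums posterior mass over
models containing k; the model-averaged effect additionally weights each
model's posterior-mean coefficient, back-transformed through the column
scales. Because the ridge prior shrinks aggressively at high
signal-to-noise, MACE magnitudes understate θ; the method is a ranking
device, and effect sizes should be read from the MR estimators instead.

**Permutation p-values** permute the (βʸ, seʸ) pairs jointly across
variants — breaking exposure–outcome linkage while preserving the exposure
correlation structure the MIPs condition on and the outcome SE
distribution — and recompute MIPs per permutation; pₖ = (1 + #{perm MIPₖ ≥
observed})/(n_perm + 1). Multiplicity is handled by BH over the K
permutation p-values (major-lipids layout) or by the Nyholt
effective-test adjustment (subfraction layout, where the ten particle
traits are strongly correlated): Meff = 1 + (K−1)(1 − Var(λ)/K) with λ the
eigenvalues of the trait correlation matrix and Var their *sample*
variance (ddof = 1), giving Meff = K for independent traits and Meff = 1
for a rank-one correlation; adjusted p = min(1, p·Meff). Corrected
p-values are by construction never smaller than uncorrected ones. MIP ties
in the report break by ascending permutation p, then name, so reports are
deterministic.

**Diagnostics.** Per-variant Cook's distances and squared standardized
residuals are computed from the weighted fit of the highest-posterior
model; variants exceeding 4/J (configurable) are flagged for a
refit-without-outliers sensitivity analysis.

## Drug-target MR and the ratio of effects

Instruments for a gene-region (drug-target proxy) analysis are exposure
associations at p < 5×10⁻⁸ inside the gene body ± 200 kb (1-based, closed
interval on both ends), greedily LD-pruned at r² < 0.1 in ascending
p-value order — deliberately permissive so correlated cis variants remain,
which is why estimation is GLS with the region LD. Estimates are reported
per 1-SD exposure *decrease* (the drug-effect convention; signs and CIs
negate). MR-Egger runs as a sensitivity analysis only when more than two
variants are available. An empty region is a reported outcome, not an
error. The pooled union of all gene instruments forms the polygenic row.

The between-outcome comparison is the ratio of log-odds effects θ_A/θ_B
with a percentile bootstrap: variant indices are resampled with
replacement once per replicate and applied to both outcomes' IVW fits
jointly whenever the panels share a variant set, preserving cross-outcome
dependence (the conservative choice for ratio CIs; independent resampling
is used otherwise). Replicates with |θ_B| < 1e−4 are excluded and counted
rather than producing unbounded ratios. The two-sided p tests ratio = 1
with the add-one correction. Single-variant panels admit no resampling
variation and return a flagged degenerate zero-width interval. Variant
resampling (rather than parametric redraws of effect estimates) is the
implemented scheme; a parametric mode would be a natural extension.

## TWAS

The gene association statistic is the standard summary-form weighted
Z-score Z_g = Σₗ wₗσₗZₗ / sqrt(wᵀSRSw), with per-variant genotype SD
σₗ = sqrt(2·eaf(1−eaf)) under Hardy–Weinberg — the usual substitute when
reference genotypes are unavailable. Weighted variants missing from the
GWAS are dropped and counted; coverage below 50% flags the gene. FDR is
computed per trait before classification, and the shared/unique partition
is over genes with q < 0.05 for either trait. Zdiff is offered in two
modes — `signed` (effect₁ − effect₂) and `magnitude` (|effect₁| −
|effect₂|) — because both definitions appear in applied work; every report
names the mode used.

Note an inherent property of BH classification: with R discoveries the
expected number of null genes crossing q < 0.05 is ≈ 0.05·R regardless of
the gene universe size, so "perfect" set recovery on a fixture is not a
statistically reasonable target; validation therefore checks that every
designed effect gene lands in its designed partition, and reports
false-positive counts separately.

## Synthetic study conditions

The generators emulate the statistical structure of a lipoprotein /
atherosclerosis study, not its biology:

* **Instrument panel**: J = 150 variants (matching a ~145-instrument
  genome-wide panel), MAF ~ U(0.05, 0.5).
* **Exposure associations**: a sparse latent factor model B = ΛΓᵀ + E.
  Each variant loads on one of F factors (loading SD 0.03, a typical
  per-allele effect in SD units for genome-wide-significant lipid
  variants); Γ gives each exposure a primary factor plus 0.3–0.7
  cross-loadings, and E adds unique noise (SD 0.7×0.03). This induces
  cross-trait genetic correlations in the 0.3–0.8 range, the regime in
  which model averaging must separate correlated candidates.
* **Outcome**: βʸ = Bθ + α with a sparse causal θ (presets: ApoB causal
  at 0.14 log-odds/SD among 5 major lipids with F = 2; XS.VLDL.P causal at
  0.14 among 10 subfractions with F = 3 — 0.14 ≈ −ln(0.87), a realistic
  per-SD atherosclerotic effect) and optional direct effects α
  (exclusion-restriction violations), zero by default.
* **Noise**: observed estimates add Gaussian noise with the closed-form
  SEs 1/sqrt(2·maf(1−maf)·n); n = 361,194 for exposures and an effective
  n_eff = 4/(1/31,307 + 1/211,753) for the binary outcome (large-biobank
  and case-control scales). Noise is independent across variants in the
  pruned-panel regime; a correlated-noise mode (covariance ∝ LD) serves
  gene-region fixtures, whose marginal effects are R·γ with two causal
  variants per region.
* **TWAS fixtures**: per-gene sparse weights over cis variants with AR(1)
  LD; under the null the variant Z-vector is N(0, R) so gene Z-scores are
  standard normal; a designed gene effect μ shifts the variant Z along
  R·S·w/σ_g so the gene-level Z has mean exactly μ. A cross-trait mode
  draws latent effect pairs with the latent correlation chosen so the
  *observed* Z correlation (signal + unit noise) hits the requested value.

Everything is reproducible bit-for-bit from the seed. What these fixtures
do **not** emulate: winner's-curse selection, sample overlap between
exposure and outcome GWAS, population stratification, non-Gaussian effect
size distributions, allele-frequency–dependent architectures, and real LD
beyond block AR(1). Passing tests therefore demonstrate correctness of the
estimators and calibration under the stated generative model, not
robustness to those real-data complications.

## Numerical choices

* LD matrices with smallest eigenvalue < 1e−8 receive a doubling diagonal
  ridge until PSD, then are renormalized to unit diagonal; the action is
  recorded. GLS solves use Cholesky factorization; a singular Ω raises a
  clear error advising regularization.
* Greedy LD pruning visits variants in ascending minimum-exposure-p order
  with lexicographic variant-id tie-breaks — deterministic given input.
* Palindromic (A/T, C/G) variants are dropped by default; the frequency
  fallback requires both allele frequencies beyond 0.08 from 0.5 and
  infers orientation from whether they fall on the same side of 0.5.
  Indels and non-ACGT alleles are rejected at load.
* The pipeline derives per-stage child seeds via
  `numpy.random.SeedSequence([global_seed, stage_index])`; persisted
  outputs contain no wall-clock timestamps, so identical (config, seed)
  runs are byte-identical.
* Permutation counts use a 1e−12 slack when comparing permuted MIPs to the
  observed MIP so exact ties at 1.0 count as exceedances.

## Problem sizes used in validation

The test suite and the acceptance script run at the preset study scales
(J = 150, K = 5 or 10) with 100 seeds for recovery rates, 200 null panels
× 199 permutations for type-I calibration, 10 seeds for TWAS split
recovery, and reduced bootstrap/permutation counts (a few hundred) inside
the end-to-end determinism checks; these sizes give stable Monte-Carlo
estimates at interactive runtimes.

## Known limitations

* No weighted-median/mode estimators, Steiger filtering, colocalization,
  or stochastic model search for K > 20.
* MACE magnitudes are shrinkage-biased (see above); ranking is the
  supported use.
* The LD-aware bootstrap resamples variants, which treats the LD matrix as
  known; uncertainty in reference-panel LD is not propagated.
* One LD panel per analysis is assumed; multi-ancestry harmonization is
  out of scope.
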