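# Methods

This note documents the statistical models implemented in `gibnet`, the
defaults and numerical choices, and what the synthetic-data validation does
and does not establish.

## LD score regression

Per-SNP association statistics are regressed on LD scores: χ² = z² for one
study, the product z_a·z_b for two. The intercept is always free — in the
univariate model it absorbs confounding (its deviation from 1 is the usual
stratification diagnostic), in the bivariate model it absorbs sample
overlap, so overlapping cohorts need no special handling. The slope is
rescaled to h² (or ρ_g) by M / mean(N), with M the number of regression
SNPs in the chromosome subset being analyzed; this self-consistent M
convention matters only for scale and cancels in genetic correlations.

Estimation is a deterministic two-pass weighted least squares. Pass one is
unweighted and yields provisional variance parameters; pass two applies
heteroscedasticity weights

- univariate: w_j = 1 / (2 ℓ_j (1 + N h² ℓ_j / M)²),
- bivariate: w_j = 1 / (ℓ_j [(1 + N_a h²_a ℓ_j/M)(1 + N_b h²_b ℓ_j/M) + (√(N_aN_b) ρ_g ℓ_j/M + intercept)²]),

the standard inverse approximate-variance forms. A self-pair (a = a) is
routed through the univariate weights so that the self-covariance equals the
heritability exactly.

Standard errors come from a delete-block jackknife over contiguous blocks in
genome order, 200 blocks by default, falling back to ⌊M/10⌋ when fewer than
400 SNPs are available. `build_gencov_matrix` runs all P(P+1)/2 regressions
on **one shared block partition**, so the jackknife covariance V of the
half-vectorized elements captures cross-element sampling covariance — the
property the downstream weighted factor fit relies on. Regression weights
are held fixed across leave-one-out replicates (the usual convention; the
jackknife then has closed form in the block-wise sufficient statistics).

## Standardization and the unit diagonal

Factor models are fitted on the genetic correlation scale. V is propagated
through r_ij = s_ij / √(s_ii s_jj) with the full delta-method Jacobian,
including the dependence on the diagonal elements. A consequence embraced
deliberately: the standardized diagonal is identically 1, so its sampling
variance is (numerically) zero. The DWLS fit therefore treats the diagonal
as an exact constraint — residual variances are profiled out as
θ_i = s_ii − (ΛΦΛᵀ)_ii, clipped at zero (clipping flags a Heywood case) —
and the weighted sum runs over the elements with positive sampling variance.
Degree-of-freedom bookkeeping is unaffected: P(P+1)/2 minus all free
parameters (θ counted) equals the off-diagonal count minus the measurement
parameters.

Empirical LDSC matrices can be indefinite; `smooth_to_pd` clips eigenvalues
at 10⁻⁶ and rescales to preserve the diagonal (a bitwise no-op on matrices
already positive definite). Only the EFA input is smoothed; the CFA operates
on raw moments through the weighted discrepancy.

## Factor discovery protocol

EFA uses minimum-residual extraction (uniquenesses optimized by L-BFGS-B,
loadings from the truncated eigendecomposition) and promax(4) rotation.
Rotation choice is a design decision: the discovery targets correlated
anatomical factors, so an oblique rotation is required for loading
thresholds to be meaningful; promax is the common default. Varimax (the
promax pre-step) is computed by pairwise Jacobi rotations with the
closed-form angle; a small deterministic pre-rotation breaks the exactly
balanced loading configurations at which the rotation criterion has zero
gradient. Factor sign indeterminacy is resolved by making each factor's
largest-magnitude loading positive.

Model building carries forward positive rotated loadings strictly greater
than τ, testing τ = 0.3 and τ = 0.5; cross-loadings are kept wherever they
clear τ, factors reduced below two regions are dropped, and structurally
identical candidates arising from different (k, τ) pairs are deduplicated
before fitting. Fitted candidates are pruned by repeatedly removing the
least significant free loading (two-sided Wald p > 0.05 — α is a
convention, configurable), refitting after each removal, never reducing a
factor below two regions, with ties broken by factor then region label so
the procedure is deterministic.

Fit statistics: χ² is the residual-based quadratic form
r'(V⁻¹ − V⁻¹Δ(Δ'V⁻¹Δ)⁺Δ'V⁻¹)r using the **full** V (DWLS point estimates,
full-V inference); AIC = χ² + 2·n_free (the χ²-based convention, documented
rather than assumed likelihood-based); CFI uses the independence
(diagonal-only) baseline; SRMR is the RMS standardized residual over unique
elements. Selection minimizes AIC among converged candidates, ties broken
toward fewer factors, then fewer free parameters. Bifactor and higher-order
models are not implemented.

## Latent GWAS

For each SNP the standardized SNP–phenotype covariances (z_p/√N_p)·sd(G),
sd(G) = √(2·maf·(1−maf)), are appended to the model covariance; sampling
variances of these elements are var(G)/N_p, independent of the LDSC block;
the genotype variance itself is treated as known. The default "fixed" mode
holds Λ, Φ, Θ at the no-SNP solution, making the joint SNP→factor estimate a
closed-form weighted least squares — vectorized over the whole panel.
"refit" mode re-minimizes the full discrepancy per SNP (measurement block
keeping its DWLS weights) and agrees with the fixed mode within a few
percent for weak effects; it exists to mirror the full per-SNP re-estimation
convention at a ~100× time cost.

The reported β is the per-allele effect on the standardized factor; for a
degenerate single-indicator factor it reduces to the SNP's per-allele
standardized regional effect. Genome-wide significance is p < 5×10⁻⁸. Locus
definition is a deterministic greedy clump: within each factor, the most
significant unassigned GWS SNP claims all GWS SNPs within ±250 kb on its
chromosome (a desk-scale substitute for reference-panel LD clumping — no LD
information is used). λ_GC = median(z²)/0.45494; the LDSC intercept of a
factor GWAS is computed with the mean regional N as the effective sample
size, a reporting convention rather than a derived quantity. Q-type
heterogeneity statistics are not computed.

## Overlap statistics

Networks and parcels are sets of region labels from a declared universe
(the 34 Desikan-Killiany names ship with the package, as do the published
SA1–SA6 and CT1–CT4 memberships). Dice = 2|A∩B|/(|A|+|B|), optionally
weighted by per-region sizes supplied as a table — the label-set statistic
has the same structure as a volumetric Dice, with region volumes playing
the role of weights; volumetric rasters are out of scope. The permutation
null redraws the *network* uniformly without replacement from the universe
(the parcel stays fixed), 1,000 iterations by default, with the add-one
Monte-Carlo p-value (1 + #{null ≥ observed})/(1 + n_iter), which is valid
and never exactly zero. With unweighted sets the null Dice is discrete, so
null p-values are super-uniform rather than uniform; with continuous
weights they are approximately uniform. FDR control is Benjamini-Hochberg.
Region names are matched case-, whitespace-, underscore- and
hyphen-insensitively; unknown names are errors, never silent drops.

## Synthetic data

The generator samples z-statistics directly from the LDSC moment model:
z_j ~ N(0, C_j) with C_j = D_N^{1/2}(Σ_g ℓ_j/M)D_N^{1/2} + C_e, where C_e
has unit diagonal and off-diagonal `overlap_rho` (phenotypic correlation ×
overlap fraction). It is a model-level simulator — no genotypes, no
realistic LD matrices, no annotation-dependent architecture — chosen for
exact control of Σ_g and speed. What passing recovery tests show is that
the estimators correctly invert the model they assume; robustness to model
misspecification (real LD, MAF-dependent architecture, population
stratification) is *not* demonstrated here.

Defaults define the study conditions: P = 12 regions, k = 2 factors with
block loadings 0.5–0.8 and factor correlation 0.45, per-phenotype h² = 0.3,
N = 30,000, M = 20,000 SNPs in LD blocks of 50 sharing one LD score drawn
from 1 + Gamma(4, ·) with mean 10, chromosomes 1–22 receiving contiguous
block shares, MAF uniform on [0.05, 0.5], sample-overlap intercept 0. The
reduced dimensions (12 regions for 34, 2 factors for 6/4, 20k SNPs for ~1M)
keep a 20-seed full-pipeline study to about half a minute while leaving the
per-SNP signal N·h²·ℓ/M in a regime where LDSC has real work to do (mean
χ² ≈ 5). The factor correlation 0.45 sits in the oblique regime the method
assumes while keeping the two factors clearly separable at this panel size.
Injected SNP effects shift z_p by √N_p·λ_p·a·√(2·maf(1−maf)), making the
per-allele effect `a` the estimand of the latent GWAS.

## Numerical details

- Jackknife blocks are contiguous in genome order; at least 2 are required.
- The CFA optimizer is L-BFGS-B with a second deterministic start if the
  first fails; factor-correlation parameters are bounded in (−0.99, 0.99)
  with an eigenvalue penalty keeping Φ positive definite for k ≥ 3.
- Sandwich covariance and fit-statistic quadratic forms use pseudo-inverses
  so rank-deficient V (or zero-variance elements) cannot produce spurious
  precision.
- File round trips write floats with `repr` (shortest exact form) and parse
  with exact string→double conversion; panels round-trip bitwise.
- Duplicate rsIDs keep the first occurrence; palindromic (A/T, C/G) SNPs
  are always dropped at harmonization since strand cannot be resolved
  without allele frequencies.

## Known limitations

- Real-data SNP QC (HapMap3 restriction, INFO filtering, MHC exclusion) is
  the caller's responsibility; the package applies only the generic min-N
  and |z|-cap filters.
- Partitioned/annotation-stratified LDSC and constrained-intercept modes are
  not implemented.
- Locus clumping ignores LD; counts are comparable between runs of this
  package but not to reference-panel-based locus definitions.
- The permutation null samples regions uniformly; volume-weighted sampling
  of null networks is not implemented (weights enter only the Dice value).
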