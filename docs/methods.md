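# Methods

## Trait model and estimation

The phenotype is modeled as `y = Xb + Σ_c g_c + e`, where each genetic
component `g_c ~ N(0, σ²_c A_c)` is governed by a relatedness matrix built
from a set of SNPs, and `e ~ N(0, σ²_e I)`. SNP-heritability of component
c is `h²_c = σ²_c / Σ σ²`. Fixed effects `X` (an affine column plus, in
cohort analyses, the top principal components) are never the candidate
SNPs themselves: conditioning on a SNP in strong LD with the component's
markers absorbs genuine signal and deflates the estimate, so known
associations are handled through the separate h²gwas/h²joint regressions
instead.

Variance components are estimated by restricted maximum likelihood with
Average-Information updates:

* gradient `dL_i = −½ [tr(P A_i) − yᵀ P A_i P y]` and AI matrix
  `AI_ij = ½ yᵀ P A_i P A_j P y`, with `P` the usual REML projection;
* a Newton step on all components, with an active-set reduction: any
  component pinned at the lower bound with a negative gradient is frozen
  and dropped from the step. If the AI step fails to improve the
  restricted likelihood or leaves the feasible region, a single EM step is
  taken instead;
* components are clamped at `1e-6 · Var(y)`; starting values are
  `Var(y)/(k+1)` per component;
* convergence requires both `|Δ log L| < 1e-4` and a maximum relative
  parameter change below `1e-6`, within 100 iterations;
* the inverse of the final AI matrix is the covariance of the component
  estimates; h² standard errors follow by the delta method using the full
  covariance.

Single-GRM fits are solved in the eigenbasis of the GRM: one `O(n³)`
symmetric eigendecomposition, after which every iteration costs
`O(n p²)`. Multi-component fits use a dense Cholesky path. Fitting two
identical covariance structures (including a GRM numerically equal to the
identity) is refused as non-identifiable.

On problems small enough to check exhaustively (n ≤ 50), the optimizer's
restricted likelihood matches a dense two-dimensional grid search to three
decimals (enforced in the test suite).

### Liability scale

For ascertained case-control traits, observed-scale estimates are mapped
to liability via `h²_liab = h²_obs · K²(1−K)² / (z² P(1−P))`, with K the
population prevalence, P the sample case fraction, and
`z = φ(Φ⁻¹(1−K))` the normal density at the liability threshold. The map
is linear, so every ratio, z-score and p-value the package reports is
invariant under it. No additional correction for ascertainment-induced
attenuation of the observed-scale estimate itself is applied.

## LD adjustments

All constructions first mean-impute missing dosages per SNP, then center
and scale each SNP to unit sample variance (empirical standard deviation,
ddof 0). All are invariant to allele-orientation flips.

* **Standard**: `A = Z Zᵀ / m`; every SNP carries weight 1.
* **Pruned**: a 50-SNP sliding window (step 5) removes the marker with
  the most pairs above r² = 0.3, greedily, ties to the leftmost; the
  standard GRM is built on the survivors.
* **LD-residual**: sweeping left to right within each chromosome, SNP j
  is replaced by the residual of its least-squares regression on all SNPs
  in the preceding 100 kb (500 kb is the conventional choice for
  imputed-density panels). One of any predictor pair with r² ≥ 0.95 is
  dropped (leftmost kept) so the normal equations stay well conditioned;
  a ridge of `1e-6 ·` (window size) is the fallback if they are still
  singular. The GRM is `R Rᵀ / Σ_j var(r_j)`: the summed residual
  variances, not the SNP count, are the normalizer, and they double as an
  "effective SNP count" (a duplicated SNP has residual variance 0 and
  simply vanishes). A `reverse` flag reruns the sweep right-to-left as an
  order-robustness check. The r² cap value is a package default — the
  requirement is only that capping precede the inversion — and is exposed
  as a parameter.
* **LD-shrink**: over the 150 index-nearest markers on the same
  chromosome (split evenly around j), `w_j = 1/(1 + #{r² > 0.2})`;
  columns are scaled by `√w_j` and the GRM normalized by `Σ w_j`. The
  published description of this weighting leaves the exact functional
  form open; this reconstruction satisfies the defining behavior (a
  perfect proxy pair shares one SNP's worth of weight, a proxy triple
  one third each).

For locus-restricted analyses, each locus is adjusted independently —
regression windows never cross locus boundaries — and the adjusted blocks
are pooled into a single GRM normalized by the summed post-adjustment
variances.

## Locus pipeline

* `define_loci` centers a window (default 1 Mb; a sweep command covers
  100 kb–2 Mb) on each catalog SNP, merges overlaps, subtracts exclusion
  regions (the MHC, chr6:26–34 Mb, by default), and computes three
  genome-fraction metrics ρ: physical bp, SNP count, and LD-residual SNP
  variance. For a merged multi-hit region only the first-listed catalog
  SNP enters the h²gwas index list.
* `h2_gwas` is the R² of the joint index-SNP model beyond the
  covariates-only model, shrunk by 1/N per fitted SNP and floored at 0.
* `h2_joint` seeds a forward-stepwise model with the index SNPs forced
  in; locus SNPs pre-screened univariately at 0.05/m enter while their
  conditional p-value stays below 0.05/m (Bonferroni on the m candidate
  SNPs, deliberately laxer than a genome-wide threshold); the final R² is
  shrunk by 1/N per SNP predictor.
* `h2_local` fits the single-component REML model on the per-locus
  adjusted GRM.
* `local_expectation` composes the chance expectation as
  `h²gwas + (h²_global − h²gwas) · ρ`: the known single-SNP contribution
  plus the rest of the genome-wide heritability landing in the loci at
  rate ρ. The composition reduces to `h²_global` at ρ = 1 and to
  `ρ · h²_global` when h²gwas = 0 (the cross-trait case, available as
  `composition="rho-only"`). No noise is modeled on the expectation: the
  estimate and expectation share SNPs and samples, so the models are
  nested rather than independent. An optional genic adjustment splits ρ
  into genic/non-genic parts (genic = within 10 kb of exons) and scales
  each by the per-class heritability density from a two-component
  genome-wide fit; it reduces to the uniform form when the loci's genic
  share matches the genome's.
* Significance is a one-sided upper-tail z-test on the analytical SE. An
  empirical alternative redraws the same number of same-sized random
  windows (excluding the trait's own loci in cross-trait mode),
  conservatively scores each draw's excess with h²gwas = 0, and reports
  `p = (#{excess ≥ observed} + 1)/(R + 1)` — the +1 convention avoids
  p = 0 at the resolution floor.

## Quality control

SNP filters run in a fixed order (first failure reported): MAF ≥ 0.01,
missingness ≤ 0.002, exact Hardy-Weinberg p ≥ 0.01, differential
missingness p ≥ 0.05. The HWE test enumerates the exact conditional
distribution of the heterozygote count (no mid-p); in case-control data it
is evaluated in controls only, which is standard practice. Differential
missingness uses Fisher's exact test when any expected cell is below 5,
else the chi-square test. Relatedness pruning removes, greedily by degree,
one of any sample pair with GRM covariance above 0.05 (a package default,
exposed as a flag). PCA outlier removal recomputes the top 20
eigenvectors for up to five rounds, dropping samples more than 6 SD from
the mean on any axis. Case-control matching weights each eigenvector by
its squared phenotype correlation and greedily pairs each control (input
order) with its nearest unused case.

## Synthetic data

The genotype generator draws, per chromosome, two latent Gaussian AR(1)
haplotypes per sample with lag-one correlation `ld_rho`, thresholds each
site at the normal quantile of its drawn allele frequency, and sums the
haplotypes. Positions accumulate exponential gaps with mean `bp_spacing`.
The MAF spectrum is uniform on (0.01, 0.5) by default; a two-class
mixture (`low_freq_fraction` of SNPs drawn from 0.02–0.045, the rest from
0.12–0.5) guarantees that class-restricted causal architectures —
low-frequency MAF < 0.05 versus common MAF > 0.10 — can always be
satisfied, with margin against sampling drift across the class
boundaries. Carrier permutation independently permutes each SNP's dosage
vector, preserving allele frequencies exactly while destroying LD. All
randomness derives from one seed through named substreams (genotypes,
positions, causals, effects, noise, permutation, loci, ascertainment), so
any stage can be re-rolled independently.

Trait architectures:

* **Genome-wide**: `n_causal` SNPs (default 5,000) drawn without
  replacement, a fraction F from the low-frequency class and the rest
  from the common class; allelic effects either standard normal
  (`allelic_normal`) or with variance `1/(2p(1−p))` (`equal_variance`,
  the default — every causal explains equal variance in expectation).
* **Local**: `n_loci` (default 180) disjoint windows of 1 Mb, each
  centered on its seed causal with ±10% uniform jitter, holding 1–10
  causal variants of one MAF class; default target heritability 0.1.
  The idealized GWAS SNP per locus is the typed marker maximizing the
  squared noise-free marginal effect `(Σ_c β_c r(t,c))²`.

Noise is centered, its sample covariance with the genetic value removed,
and its variance scaled to `Var(g)(1−h²)/h²`, so the realized sample
heritability equals the target to machine precision — recovery targets in
tests are sharp, not approximate.

The generator emulates LD decay, a two-class MAF spectrum and polygenic
architectures. It does **not** emulate population structure or admixture,
genotyping batch effects, very rare variants (MAF < 1%, where normality
assumptions on normalized effects degrade), mutation/recombination-based
haplotype sharing (no coalescent), or imputation uncertainty. Passing
tests therefore certify the estimators' behavior under the stated
generative model, not robustness to those real-data complications; the
latent-AR(1) LD model was chosen because it gives closed-form control of
LD decay, which is the mechanism under study.

## Simulation sizes

The test suite and acceptance script use desk-scale problem sizes chosen
as the smallest that express each mechanism cleanly: idealized-tagging and
local-calibration checks use 300 samples × 5,400 SNPs spanning 180
one-megabase loci; the LD-free unbiasedness check uses 10 replicates of
2,000 samples × 10,000 SNPs with 5,000 causals (the causal MAF mix F
cycles through 0, 0.5, 1, with the panel's low-frequency share set to
0.2 + 0.6 F so each class can supply its draw); the LD-deflation
comparison uses 8 replicates of 500 samples × 4,000 densely spaced SNPs
(latent adjacency correlation 0.95) with all 300 causals low-frequency;
standard-error calibration uses 30 replicates of 300 × 1,000. Estimator
properties at these sizes (unbiasedness without LD, direction of LD bias,
SE calibration) are scale-stable; absolute standard errors of course
shrink with n.

## Known limitations

* Observed-scale case-control estimates from strongly ascertained cohorts
  can be attenuated in ways the linear liability map does not undo; the
  package reports the transform as-is.
* The stepwise h²joint inherits the usual instability of forward
  selection under strong collinearity; collinear candidates are skipped,
  not orthogonalized.
* `empirical_null` refits a variance component per draw; with thousands
  of draws on large cohorts this is the dominant cost and is best run
  with the standard adjustment.
* Bivariate/multi-trait REML and winner's-curse effect-size corrections
  are out of scope; relative (gain) comparisons are expected to absorb
  uniform effect-size inflation.
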