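# Methods

This note documents the models behind pleioscan, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model and conventions

Summary statistics are per-variant records (chromosome, 1-based position,
effect/other allele, effect β on the A1 scale, standard error, p-value,
sample size). Only biallelic autosomal SNPs are kept: indels, multi-allelic
sites and non-autosomes are dropped on read, matching the biallelic
convention of the usual LD reference panels. Odds ratios are converted by
natural log. P-values of zero are clipped to 1e-300 so downstream log-space
statistics stay finite. Region-exclusion windows (e.g. the MHC,
chr6:25726291–33377699 in hg19) are inclusive on both ends.

Allele harmonization aligns every table to a reference trait: swapped
A1/A2 flips the β sign, incompatible allele pairs are dropped, and
strand-ambiguous A/T and C/G variants can be dropped behind a flag. These
policies are conventional defaults — sources differ on ambiguous-SNP
handling, so the flag defaults to off and the operation is involutive
either way. Multi-trait alignment uses strict intersection (no imputation);
panels carry a z matrix, a p matrix and per-trait group labels
(region_area, region_thickness, disorder).

## Synthetic data generator

The generator emulates the features of the target study design that the
pipeline's statistics actually depend on:

- **Sample overlap** appears only as residual z correlation across traits
  (`residual_cov`, unit diagonal), which is exactly what the whitening stage
  consumes. The brain/disorder preset uses a dense region block
  (off-diagonal 0.3 by default — a placeholder magnitude, not an empirical
  estimate) and identity correlation for disorders.
- **Causal architecture** is point-normal per trait: a fraction π of
  variants carries effects β ~ N(0, σ_β²) on the standardized-genotype
  scale, so h² = Mπσ_β² with no allele-frequency bookkeeping. Pairwise
  overlap is drawn jointly: a shared fraction π₁₂ with bivariate-normal
  effects of correlation ρ₁₂ inside the shared component. Explicitly
  planted variants with fixed effects support targeted power scenarios.
- **LD** is block-diagonal with constant within-block genotype correlation
  r, giving closed-form LD scores ℓ = 1 + (b−1)r². The z signal of variant
  j is √n·(Rβ)ⱼ with R the block correlation matrix. Genotype matrices for
  r² computation are generated by dichotomizing a latent Gaussian at zero
  with latent correlation sin(πr/2), which yields binary correlation r at
  50% allele frequency.
- Variant coordinates place each LD block on its own 2 Mb island so blocks
  are separated by more than any clumping window.

Not modeled: allele-frequency spectra, MAF-dependent architectures, sex
chromosomes, population structure, real LD patterns, shared individuals.
Consequently, passing tests demonstrate the correctness and calibration of
the statistical machinery under its stated assumptions — not robustness to
the messiness of real GWAS (stratification, cryptic relatedness,
frequency-dependent effects).

## Whitening

The cross-trait null covariance C is estimated as the sample covariance of
z over variants where every included trait has |z| below a cap (default 2;
∞ disables it). The cap keeps true signal from inflating the correlation
estimates; the estimator itself is a pragmatic choice, as is the shrinkage
repair — if the smallest eigenvalue falls below 1e-8 of the largest, C is
shrunk toward the identity in steps of 0.05 until well-conditioned, with a
warning. At least 500 masked variants are required.

The transform is z̃ = L⁻¹z with C = LLᵀ (Cholesky). This is triangular and
therefore order-dependent: trait j's whitened score involves only traits
1..j. The ordering is fixed and recorded in the model; a symmetric
inverse-square-root (ZCA) operator is available behind a flag for users who
prefer an order-free transform. P-values are recomputed as two-sided normal
tails of z̃ — recomputation is an assumption about how decorrelated
per-trait significance should be defined, flagged as such. By default only
the same-cohort region block is whitened; disorder traits from disjoint
cohorts pass through raw.

## Subset scan

Per-trait evidence is the rank-uniform score u = rank(p)/(M+1) (average
ranks on ties; a raw-p mode exists behind a switch). Ranks make the scan
robust to per-trait miscalibration and give marginally uniform scores by
construction.

A design names required traits, an optional pool, and a minimum number of
optional traits. Optional traits are filtered at m^(−3/2) where m is the
design size — the exponent is configurable; 3/2 reproduces the 3.9e-4
filter of the 186-trait joint design. Required traits bypass the filter
(otherwise the all-disorders design would discard nearly every variant).

For fixed subset size the minimal score sum is attained by the smallest
u values, so searching prefixes of the ascending-sorted candidates is
exhaustive over all admissible subsets (asserted against a brute-force
enumeration oracle in tests). The Irwin–Hall lower tail converts a sum s of
k uniforms to a per-subset p-value, computed as exp(k·ln s − ln k!) for
s ≤ 1 and by the alternating finite sum (with the s ↔ k−s symmetry)
otherwise.

**Multiplicity.** Selecting the j smallest filtered scores makes the raw
Irwin–Hall tail anti-conservative, and correcting only for the number of
prefixes evaluated is not enough: the selection itself must be paid for.
Because the j smallest candidates minimize the sum over all C(O, j) size-j
subsets of the pool, the union bound gives a valid per-size p-value
q_j = min(1, C(O, j)·IH(k_req + j, s_j)); the reported corrected p-value is
the Bonferroni sum min(1, Σ_j q_j) over evaluated sizes, and the reported
best subset minimizes q_j. Measured on simulated global nulls (M = 200,000,
10 independent traits) the empirical call rate at α = 1e-3 is 0.8–1.1e-3
across seeds and falls below nominal in the far tail — calibrated at
moderate thresholds, conservative where it matters. Monotonicity holds in
the natural sense: lowering the score of a trait that is already a
candidate never increases the corrected p-value (lowering a non-candidate
below the filter adds a term to the correction and can legitimately
increase it).

Genome-wide significance uses α = 5e-8 on the corrected p-value. The
three-stage suite builds per-disorder designs (one disorder required),
dimension-group designs (a disorder group required), and the
general-psychopathology design (all disorders required), each with the
region pool optional.

## Clumping

Greedy by ascending p-value (the standard PLINK/FUMA convention; the
iteration order is a convention, not a theorem): a variant is kept as
independent-significant iff r² < 0.6 with every kept variant on the same
chromosome within the LD window (1 Mb default; r² is 0 beyond it and across
chromosomes). Independent SNPs merge into loci when within 250 kb (chained
along the chromosome) OR in r² ≥ 0.1 — both rules are toggleable since
either convention appears in practice; the OR combination is the default.
Leads are the lowest-p locus members; because any r² ≥ 0.1 pair shares a
locus, leads of distinct loci are in r² < 0.1 by construction. Missing LD
for a same-window pair degrades to r² = 0 with a warning rather than an
error.

## Causal mixture models

Univariate: z ~ (1−π)·N(0, σ₀²) + π·N(0, σ₀² + nσ_β²). The likelihood is an
exact two-component mixture — no quadrature. An optional LD extension mixes
over the number c of tagged causals, c ~ Binomial(round(ℓ), π), with
variance σ₀² + c·n·σ_β²·w̄ (w̄ the mean squared LD weight), truncated at
c_max = 20. This deliberately simplifies the full convolution over
empirical LD used by reference-panel tools; the estimands (π, σ_β², h²,
overlap, ρ₁₂) are preserved at desk scale. The bivariate model is the
four-component mixture (null / trait-1-only / trait-2-only / shared) with
residual z correlation ρ₀ in every component and effect correlation ρ₁₂ in
the shared one; it is implemented in the no-LD form only.

Derived quantities: h² = Mπσ_β² on the observed scale only (no liability
transform); polygenicity-90% via the χ² threshold construction — t* solves
P(χ²₃ > t*) = 0.9 and the count is round(πM·P(χ²₁ > t*)), scale-free in
σ_β² (about 44.5% of causal variants for a normal effect distribution);
discoverability = σ_β²; overlap fractions π₁₂/(π₁+π₁₂) and π₁₂/(π₂+π₁₂);
concordance = ½ + arcsin(ρ₁₂)/π (the bivariate-normal orthant probability).
Concordance is reported from ρ₁₂ rather than by counting
posterior-assigned variants; a posterior-counting mode exists as a
cross-check, since either definition is defensible.

**Fitting.** Nelder–Mead on unconstrained transforms (logit π, log
variances, atanh correlations; the bivariate simplex via softmax logits),
with multiple deterministic-seeded starts (5 univariate, 3 bivariate)
spreading π over decades and matching σ_β² to the observed excess z
variance; bivariate starts anchor π₁+π₁₂ and π₂+π₁₂ at the univariate fits
and spread the shared fraction. Convergence tolerance 1e-8 in log
likelihood, iteration caps of 2,000/4,000. The bivariate optimizer hot path
uses a fused numba kernel; the reported log likelihood is recomputed with
the plain vectorized form. Identifiability caveat: at weak discoverability
(nσ_β² ≲ 5) the shared-fraction/ρ₁₂ trade-off is flat and single-realization
estimates can wander even when the optimizer finds the true maximum;
recovery tests therefore use nσ_β² = 20 for the bivariate case and report
medians over seeds.

**Model-fit assessment.** AIC(constrained) − AIC(full) for the
infinitesimal baseline (π = 1) in the univariate case and the zero-overlap
(π₁₂ = 0) and maximum-overlap (the sparser trait's causal set fully nested)
baselines in the bivariate case; positive gaps support the mixture.
`subsample_average` repeats a fit over k random variant subsets and reports
per-parameter means and standard errors, mirroring the practice of
averaging over reference-panel subsets.

## Locus-level summaries

Two selection modes attribute regions to a lead SNP: per-trait p < 5e-8 in
the decorrelated panel, or membership in the scan's best subset of a
significant variant (best-subset membership — rather than membership in any
admissible significant subset — is an implementation choice, noted as
such). Signed effects are always read from the original pre-whitening
panel, so direction statements refer to the per-trait GWAS scale. A profile
is consistent when all selected region effects share one sign, divergent
when at least one strictly positive and one strictly negative effect
co-occur; exact zeros carry no direction and are excluded from
classifications and concordance denominators. Quartiles use linear
interpolation between order statistics (conventions differ; this one is
recomputable from the stored counts). Concordance intervals are
Clopper–Pearson at 95%.

## Problem sizes and numerical choices

Test and example problem sizes are chosen so the whole suite runs in
minutes on one core: panels of 5,000–200,000 variants, 6–30 traits (the
186-trait preset is exercised at reduced variant count), mixture fits at
M = 100,000, Monte-Carlo oracles at 10⁶ draws. Calibration checks use
elementwise tolerances of 4/√M for covariance contracts and binomial-width
margins for rate checks. Ties in ranks use average ranks with equal-score
ordering by trait index; all simulations and fits are deterministic given
their seeds.

## Known limitations

- The scan's correction is a union bound: conservative in the far tail, so
  genome-wide power at 5e-8 is slightly below an exact selective-inference
  calibration.
- The mixture models ignore LD beyond the binomial LD-score approximation
  (univariate only) and assume MAF-independent effects on the standardized
  scale.
- Whitening assumes the estimated null covariance applies at signal
  variants; strong signal in early-ordered traits can leak into
  later-ordered whitened scores (the triangular transform's
  order-dependence), which is why signed direction profiles are read from
  the original panel.
- Heritability is observed-scale only; no liability transform for
  case-control traits.
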