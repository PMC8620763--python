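# Methods

This note documents the statistical models implemented in mrkit, the
conventions and defaults chosen where the literature admits variants, what
the synthetic-data generator does and does not emulate, and known
limitations.

## Summary-statistic conventions

All tables are tab-separated with a header row; canonical columns are SNP,
CHR, POS, EA, OA, EAF, BETA, SE, P, N, N_CASES, MAC, with aliases supported
through a column map. Positions are 1-based and inclusive; strand is
implicit (forward), and strand discordance is resolved only by allele
complementing. Rows violating basic record invariants (SE ≤ 0, EAF outside
(0,1), identical alleles, case count exceeding N) are dropped on read with a
logged count rather than aborting, because isolated malformed rows are
routine in distributed summary statistics. P-values are recomputed from
beta/SE on read so that downstream thresholding is internally consistent
with the effect estimates; writers emit 17 significant digits, which is
lossless for float64 round-trips.

## Fixed-effect meta-analysis

Two exposure cohorts measuring the same standardized trait are pooled per
SNP by inverse-variance weighting: β = Σwᵢβᵢ/Σwᵢ, w = 1/SE², SE = (Σw)^−½.
Only SNPs present in both cohorts are pooled, each requiring a minor allele
count strictly greater than the threshold (default 10) in each study; the
MAC is computed from 2·N·MAF when not supplied. Cohort B is sign/strand
aligned to cohort A before pooling, and per-cohort effects are carried in
the output so that direction-consistency filters can be applied later
without re-reading the inputs.

## Harmonization

The exposure is oriented so every SNP-exposure effect is non-negative (the
effect allele is the exposure-increasing allele); the outcome is then
aligned to that allele, negating the effect and complementing the EAF on an
allele swap, and complementing allele labels when they match only on the
opposite strand. Palindromic variants (A/T, G/C) cannot be strand-resolved
from labels; they are retained only when both EAFs fall outside the
ambiguity window — default (0.42, 0.58), the common two-sample MR practice —
and agree on which allele is minor. Palindromic variants with a missing
outcome EAF are dropped (they cannot be oriented); non-palindromic variants
with missing outcome EAF proceed, since label/strand alignment does not need
the frequency. Harmonization is idempotent, never produces a negative
exposure effect, and partitions the SNP intersection exactly into retained
and dropped-with-reason.

## Instrument selection and clumping

Three strategies, mirroring common practice for metabolite exposures:

1. **functional** — a curated candidate list tested for nominal association
   with the exposure (default α = 0.05). If no candidate passes, the set is
   not carried into MR; the pipeline records the skip explicitly.
2. **pathway** — variants inside user-supplied gene regions, passing a
   Bonferroni threshold α_family/m where **m is counted from the supplied
   data** (number of exposure variants falling in the regions), not
   hard-coded; plus the common filters below. Regions supplied as BED are
   converted from 0-based half-open to 1-based inclusive on read.
3. **genome-wide** — meta-analysis p < 5×10⁻⁸ and per-cohort p < 0.01 in
   both cohorts, plus common filters.

Common filters: strict sign agreement of the per-cohort effects (zero
fails), and MAF ≥ maf_min (default 0.01) in the exposure and in **every**
outcome table (a SNP absent from an outcome fails that outcome's filter).
The MAF floor is exposed as a parameter because published descriptions of
such filters are often internally inconsistent between a percent and a
proportion reading; the default is the proportion reading (0.01).

Greedy LD clumping repeatedly takes the remaining candidate with the
smallest exposure p-value as an index SNP (ties broken by chromosome,
position, then rsID so results are order-invariant) and removes candidates
on the same chromosome within the window (default 10,000 kb) with ρ² at or
above the threshold. Distance is measured index-to-candidate, not through
transitive chains, matching standard clumping semantics. Pairs absent from
the LD matrix are treated as uncorrelated and logged.

## Estimators

All estimators use first-order (delta-method) Wald-ratio weights
wⱼ = γⱼ²/σ_Γⱼ², i.e. exposure-side uncertainty is ignored in weighting; the
Wald ratio itself exposes a second-order SE variant as an option. 95%
intervals use the normal quantile 1.959964 throughout, with no small-sample
t corrections.

- **IVW / MR-Egger SE convention.** The SE is the weighted-regression SE
  with the residual scale σ̂ floored at 1 — the fixed-effect /
  multiplicative-random-effects hybrid: under-dispersion never shrinks the
  SE below the fixed-effect value, over-dispersion inflates it
  multiplicatively.
- **Weighted median.** Ratios sorted ascending, standardized mid-cumulative
  weights sⱼ = (Σᵢ≤ⱼwᵢ − wⱼ/2)/Σw, estimate by linear interpolation at
  s = 0.5. SE by parametric bootstrap (default 1,000 draws of γ*ⱼ, Γ*ⱼ from
  their sampling distributions); the seed is a mandatory argument —
  reproducibility over convenience.
- **Weighted mode.** Normal-kernel weighted density of the ratios with
  bandwidth φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5), argmax on a 512-point grid
  spanning the ratios ± 3 bandwidths; if the MAD is degenerate but the
  ratios are not all equal, the sd is used; if all ratios coincide the
  common ratio is returned. Bootstrap SE as for the median.
- **MR-RAPS, simple variant.** The implementation maximizes the profile
  objective Σρ(tⱼ(β)) with ρ the squared-error or Huber (k = 1.345) loss by
  bounded one-dimensional minimization; no over-dispersion parameter is
  fitted. The simple variant is chosen because it is fully verifiable
  against a dense grid-search oracle. The SE is sandwich-form: the bread is
  the numerically differentiated observed score; the meat is the *expected*
  squared score under the model tⱼ ~ N(0,1), evaluated by 64-point
  Gauss-Hermite quadrature. The expected (rather than empirical) meat is
  used because with few SNPs the fitted residuals are near zero and the
  empirical meat collapses, giving absurdly small SEs; the expected-meat
  form reduces exactly to the fixed-effect IVW SE in the σ_γ → 0 limit.
- **LD-aware GLS.** β̂ = (γᵀΩ⁻¹γ)⁻¹γᵀΩ⁻¹Γ, Ω = diag(σ_Γ)·ρ·diag(σ_Γ). A
  condition number above 10⁸ raises with advice to prune |ρ| > 0.95 pairs;
  with ρ = I this reduces exactly to fixed-effect IVW.
- **Cochran's Q** uses the same first-order weights; df = J − 1.

Estimator applicability in the pipeline follows field practice: Wald
ratio/IVW always (IVW delegates to the Wald ratio at J = 1); median, mode
and Egger require more than 2 SNPs; the GLS estimator runs only at relaxed
clumping thresholds (ρ² ≥ 0.1) where correlated instruments are retained.
Skips are recorded with reasons, never silent. No multiple-testing
correction is applied across instrument sets or outcomes; intervals are
reported unadjusted.

## Instrument strength, power, directionality

Per-SNP variance explained is 2b²p(1−p)/var (symmetric in p ↔ 1−p), summed
over the set; F = r²(n−1−k)/((1−r²)k). The binary-outcome power model is
the mRnd calculation (see README for the formula); `detectable_or` inverts
it on each side of OR = 1 by Brent bisection to absolute tolerance 10⁻⁶,
growing the bracket adaptively within the range where the attenuation
constraint K(1−K) > b₀₁² holds. The R² argument is taken verbatim as
supplied: study tables often label instrument variance explained in
percent while the power calculations that produced them consumed the
printed number directly, so the caller — not the package — chooses the
scale.

The Steiger test computes exposure-side r² from Σ2γ²p(1−p) (standardized
exposure) and outcome-side r² per SNP from the association Z statistic as
Z²/(Z²+N), then compares the implied correlations with a two-sample
Fisher-z test, treating the samples as independent (true in two-sample MR).
The Z²/(Z²+N) approximation is used rather than a liability-scale
transformation because it requires no case-fraction model and is directly
testable; it slightly overstates outcome r² for very unbalanced
case-control ratios, making the forward-direction call conservative.

## Synthetic-data generator

The generator emulates the structure of a two-cohort metabolite GWAS with
case-control outcomes: defaults are exposure cohorts of 5,841 and 8,455
(total 14,296 ≈ the 14,149 effective size of the motivating design), a
120,328-sample outcome with 45.85% cases, and strata of 1,589 (51.0% cases)
and 5,660 (59.0% cases). The default panel is 45 SNPs on one chromosome in
a block-AR1 LD structure (ρ = 0.9 between neighbours), MAF ~ U(0.05, 0.5),
and per-SNP effects γⱼ ~ N(0, 0.006²), sized so the panel explains ~0.05%
of exposure variance — the weak-instrument regime of the motivating study
(0.03–0.09%). The default causal effect is zero, matching that study's null
conclusion; tests that need signal override β and the effect spread
explicitly.

Summary-level route: standard asymptotic SEs for a standardized trait,
σ_γ = 1/√(2p(1−p)N) and σ_Γ = 1/√(2p(1−p)N·K(1−K)), with estimation errors
correlated across SNPs through the LD matrix (covariance DρD) and drawn
independently between exposure and outcome samples (no sample overlap).
Directional pleiotropy αⱼ ~ N(mean, sd²) is applied to the configured
invalid fraction **relative to the exposure-increasing allele**
(Γ = βγ + α·sign(γ)): applied to the raw allele coding it would be
randomized by the γ ≥ 0 harmonization orientation and degenerate to
balanced pleiotropy, so the directional-pleiotropy knob would not act as
one.

Individual-level route: genotypes from two thresholded latent-Gaussian
haplotypes sharing the block-LD correlation (a Gaussian copula, so realized
dosage LD is close to, not exactly, the target ρ); exposure = standardized
genetic score + Gaussian noise, rescaled to unit variance; outcome from a
logistic model with age and sex covariates, the intercept solved by
bisection to hit the target prevalence; stratum membership independent of
genotype. Per-SNP scans use OLS (continuous) or IRLS logistic regression
(binary; tolerance 10⁻⁸, 50 iterations) with age and sex adjustment,
dropping non-convergent or separated SNPs with a log message.

All randomness derives from one master seed through `SeedSequence` children
with fixed stream indices (panel; the two exposure cohorts; one per
outcome; a reserved stream for the individual-level route), so identical
configs are bit-reproducible and the two routes never share a stream.

What the generator does **not** emulate: the metabolomics normalization
chain (median normalization, log transform, winsorization) upstream of the
standardized exposure; population stratification and other confounding;
sample overlap; winner's curse; realistic genome-wide LD panels. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to these real-data phenomena.

## Problem sizes used in the test suite

Operating-characteristic tests use summary-level simulation at J = 50
strong instruments (effect spread 0.15, independent SNPs) with 200
replicates for IVW coverage, 500 for type-I error, 200 forward-simulated
replicates for Steiger directionality, and 30–100 replicates for the
pleiotropy-ordering checks; these sizes give stable proportions while
keeping the default suite around a minute.

## Known limitations

- MR-RAPS is the simple variant; data with genuine over-dispersion will
  show it in Q rather than in the RAPS SE.
- The GLS estimator assumes the supplied LD matrix is measured without
  error in the same ancestry as both samples.
- The power model's attenuation approximation breaks down for extreme ORs
  (the solver reports when no root exists in the valid range).
- One-sided orientation (γ ≥ 0) makes the Egger intercept's sign
  interpretable but, as everywhere, the intercept test has low power at
  small J.
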