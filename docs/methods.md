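# Methods

This note documents the statistical procedures implemented in `mrscreen`,
the synthetic data-generating model used to validate them, the numerical
conventions, and the known limitations the validation experiments quantify.

## Two-sample MR estimators

All estimators consume a harmonized table of per-SNP exposure effects
(β̂ₓᵢ, σₓᵢ) and outcome effects (β̂ᵧᵢ, σᵧᵢ) on a common effect-allele coding;
for binary traits all effects are log-odds ratios.

**Wald ratio.** θ̂ = β̂ᵧ/β̂ₓ with the first-order delta standard error
σᵧ/|β̂ₓ| (no second-order term: the pipeline enforces strong instruments,
F ≥ 10 flagged otherwise, where the first-order approximation is standard).
β̂ₓ = 0 is a hard error.

**IVW.** Weighted least squares of β̂ᵧ on β̂ₓ through the origin with weights
1/σᵧ², equivalent to the inverse-variance-weighted mean of Wald ratios.
Fixed-effect se = (Σwβ̂ₓ²)^(−1/2). The random-effects variant is
*multiplicative*: the se is inflated by √(Q/(k−1)) floored at 1, so it
reduces exactly to fixed effects in homogeneous data. Model choice follows
the dual heterogeneity rule below.

**Cochran's Q / I².** Q = Σwᵢ(θ̂ᵢ − θ̂_IVW)² over per-SNP Wald ratios with
first-order weights wᵢ = β̂ₓᵢ²/σᵧᵢ² (identical to the IVW regression
residual sum, keeping weights consistent across modules); df = k−1;
I² = max(0, (Q−df)/Q). The random-effects model is selected iff
p_Q < 0.05 **and** I² > 0.25, both strict, both configurable — many
packages use p alone, but the dual rule is this pipeline's default.

**MR-Egger.** Every record is first re-signed so β̂ₓ ≥ 0 (the intercept is
not orientation-invariant without this convention), then β̂ᵧ is regressed
on β̂ₓ with a free intercept, weights 1/σᵧ². Coefficient standard errors use
a multiplicative over-dispersion factor max(1, RSS_w/(k−2)) — no credit for
under-dispersion. The intercept, its se and two-sided normal p-value are
reported as the directional-pleiotropy test. Requires k ≥ 3; below that a
structured "not applicable" result is returned rather than an exception.

**Weighted median.** Per-SNP ratios are sorted; with normalized weights
wᵢ = 1/se²(θ̂ᵢ) the estimate is read at cumulative weight 0.5
(cumulative sums offset by wᵢ/2, linear interpolation between bracketing
ratios). The se comes from a seeded parametric bootstrap: β̂ₓ and β̂ᵧ are
re-drawn from N(β̂, σ²) per SNP (default 1000 draws) and the sd of the
re-estimates is reported.

**Mode estimators.** Ratios are smoothed with a normal kernel of bandwidth
h = φ · 1.4826 · MAD(ratios), φ the configurable `bandwidth_factor`
(default 1). The simple mode is the argmax of the unweighted density on a
512-point grid spanning the ratio range ± 3h; the weighted mode uses
inverse-variance weights. When the MAD is zero the kernel degenerates to
point masses and the heaviest ratio wins. Density ties within floating-point
round-off break toward the smaller ratio. Bootstrap se as for the median.

All confidence intervals are normal-based (β ± 1.959964·se) and p-values are
two-sided normal, including the Egger coefficients (a deliberate convention;
packages using t-references differ slightly at small k).

## Instruments

Candidates need p below the genome-wide threshold (default 5×10⁻⁸), then
greedy LD clumping in ascending-p order (ties broken by chromosome,
position, SNP id for determinism): a candidate within the window (default
10,000 kb) of a retained SNP on the same chromosome is dropped when the
pairwise LD r² (from an optional user-supplied matrix) reaches the
threshold (default 0.001) — or unconditionally when no LD information is
available, a deliberately conservative distance-only rule that is logged.
Per-SNP explained variance uses R² = z²/(z²+n) (algebraically the
2p(1−p)β² form on the standardized scale), summed into the set-level R²
feeding F = ((N−K−1)/K)·(R²/(1−R²)). Weak sets (F < 10) are flagged, never
auto-dropped.

## Harmonization

Exposure and outcome tables are merged on SNP id (records whose id matches
but whose chromosome/position conflict are dropped and logged). Outcome
records are re-expressed on the exposure coding: label swaps negate the
beta and complement the EAF; strand complements are relabelled. Palindromic
pairs (A/T, C/G), where labels cannot distinguish a swap from a strand
flip, are oriented by allele frequency: both EAFs must lie outside the
ambiguity window [0.5−w, 0.5+w] (default w = 0.08, i.e. ambiguous within
[0.42, 0.58]); if the label-implied alignment disagrees on which allele is
minor, the outcome is re-oriented rather than dropped. Ambiguous or
frequency-less palindromes are dropped and counted; w = 0.5 drops every
palindrome (the conservative alternative). These rules make corruption an
exact round trip: estimates after corruption + harmonization equal the
uncorrupted data's to numerical precision, which is the module's primary
oracle test. Real data additionally carry EAF estimation noise between
cohorts, which can misorient palindromes near the window boundary — a
failure mode the exact oracle does not exercise.

## Steiger directionality

Instrument R² is summed per trait; the inferred direction is correct when
the exposure R² exceeds the outcome R². The p-value compares the implied
correlation magnitudes |r| = √R² via Fisher's z with variances 1/(n−3) on
each side (two-sided normal). The conclusion is antisymmetric under
swapping trait roles whenever significant.

## Two-step mediation

Indirect effect β₂β₃ (product of coefficients); first-order Delta se
√(β₃²se₂² + β₂²se₃²) — validated against a 10⁵-draw Monte-Carlo sd to
within 3% in the small-se regime; normal 95% CI; direct effect β₁ − β₂β₃;
proportion mediated β₂β₃/β₁ computed on the beta scale only (invariant to
whether results are reported as ORs). Proportions outside [0,1]
(inconsistent mediation) are flagged, never clamped. The three inputs may
come from different estimators (e.g. a single-SNP Wald total effect and a
random-effects IVW step 2); provenance is recorded. Step 2 (mediator →
outcome) must be instrumented by the *mediator's own* variants: the
exposure's instruments act on the mediator only through the exposure, and
their ratio identifies (θ + β₂β₃)/β₂, not β₃.

## Screening pipeline

Per exposure: instruments → harmonization → Wald ratio (one instrument) or
IVW with the heterogeneity-driven effects switch (several) → sensitivity
diagnostics where the SNP count permits (Q needs ≥ 2, Egger ≥ 3). Exposures
without instruments or without shared SNPs are skipped with a reason code.
`m_tested` counts analyzable exposures; the Bonferroni denominator defaults
to `m_tested` but a nominal panel size can be configured (the convention of
dividing by the full panel regardless of attrition). Replication requires
p < α/(number of discovery hits) in the second cohort *and* an identical
effect sign. Mediation runs on surviving hits. The run is a pure function
of inputs + config (bootstrap seeds included) and emits a per-stage
manifest.

## Synthetic data-generating model

Summary statistics are generated directly — two-sample MR consumes nothing
else, so no individual-level genotypes are simulated. For exposure SNP i:
maf ~ U(maf_range); γᵢ = ±√(R²/2p(1−p)) so each SNP explains exactly
`exposure_r2_per_snp` of exposure variance (sign random — allele coding is
arbitrary); mediator effect b₂γᵢ; outcome effect (θ + b₂b₃)γᵢ + sign(γᵢ)·αᵢ.
The pleiotropy term αᵢ (none / balanced N(0,sd) / directional N(mean,sd),
optionally restricted to a fraction of "invalid" SNPs) is defined in the
*exposure-increasing allele orientation* — the convention under which
"directional" pleiotropy is meaningful and which the Egger intercept
estimates — and therefore carries sign(γᵢ) on the reported coding.
Optional mediator-specific SNPs δⱼ (effects 0 on X, δⱼ on M, b₃δⱼ on Y)
provide valid step-2 instruments. Reported betas add independent
N(0, 1/(2p(1−p)n)) noise per trait (the large-sample se of a per-allele
coefficient on a standardized trait; samples non-overlapping across
traits); p-values follow from the normal z. Binary traits use the same
machinery on the log-OR scale. Ground truth: total effect θ + b₂b₃,
proportion mediated b₂b₃/(θ + b₂b₃).

Allele corruption then emulates source discordance: a configurable fraction
of SNPs is assigned palindromic pairs, and outcome/mediator rows are
randomly reported with swapped coding (beta negated, EAF complemented)
and/or strand-complement labels. Uncorrupted twin tables are retained for
oracle comparisons. SNPs are spaced 20 Mb apart across 22 chromosomes —
truly independent, beyond any clumping window — so instrument selection is
exactly testable; realistic LD structure, winner's curse and sample-overlap
bias are deliberately out of scope, so passing tests say nothing about
those phenomena in real data.

### Reference study conditions and defaults

The validation experiments (and `scripts/acceptance.py`) use: 30 instruments
(50 for pleiotropy detection), per-SNP R² = 1%, n = 10,000 per trait
(per-SNP F ≈ 100), θ = 0.3, b₂ = 0.4, b₃ = 0.5 (proportion mediated 0.4),
maf ∈ (0.05, 0.45); corruption defaults 15% palindromic / 30% swapped /
10% strand-relabelled (typical discordance between heterogeneous GWAS
releases). Pleiotropy scenarios: directional mean 0.02 with sd = mean/4
(a concentrated directional bias; power experiments use 50 SNPs), balanced
sd = 0.02 (the same |α| scale), and the invalid-instrument scenario
directional mean 0.1 on 40% of SNPs (≈ 1.7× the typical per-SNP outcome
effect). Replicate counts (300–1000 per experiment) keep the full suite and
the acceptance script to a few minutes on one CPU; Monte-Carlo standard
errors (sd/√R) are reported alongside every mean.

## Known finite-sample properties and limitations

At F ≈ 100 the panel shows the expected small-sample behaviour, which the
validation experiments measure rather than hide:

- IVW carries the weak-instrument attenuation −θ/(F+1) (≈ −0.003 at these
  conditions; measured −0.0041 ± 0.0006 over 1000 replicates). CI coverage
  remains ≈ 0.94 and type-I error ≈ 0.043.
- Ratio-based estimators with β̂ₓ²-proportional weights (weighted median,
  weighted mode) acquire an additional downward bias of similar order
  because the weights are correlated with the exposure measurement error.
- MR-Egger suffers classical regression dilution: with per-SNP R² fixed,
  the exposure-beta spread comes only from maf variation, giving a weighted
  I²_GX ≈ 0.76 here and a slope attenuation of ≈ 24% (measured slope 0.225
  for θ = 0.3). The dilution also leaks ≈ +0.012 into the intercept, and the
  multiplicative-dispersion intercept test becomes anti-conservative
  (≈ 0.08 at nominal 0.05) under strong homoscedastic balanced pleiotropy,
  because the weights are then no longer proportional to the total residual
  precision. These are properties of the standard estimators under these
  conditions, not implementation artifacts — the regressions themselves
  agree with generic weighted-least-squares references to 10⁻⁹.
- The simple mode is nearly unbiased here but is the least efficient
  estimator; its bandwidth rule (MAD-based, no k-dependence) is a
  documented convention, not an optimum.

Degenerate inputs are handled structurally: single-instrument exposures get
Wald-only output with no sensitivity analysis; k < 3 returns "not
applicable" results for Egger/median/modes; exposures losing all
instruments at harmonization are skipped with a reason code.
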