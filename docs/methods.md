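# Methods

`cliffmr` implements a two-sample Mendelian-randomization (MR) analysis of
a binary-liability exposure (schizophrenia genetic liability) on
fitness-related outcomes (number of children, age at first birth, number
of sexual partners), together with the sensitivity machinery used to
probe a cliff-edge fitness hypothesis, and a simplified LD-score
regression for genetic correlation.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Causal model and estimators

The two-sample design assumes per-SNP effects estimated in two
non-overlapping samples: β̂ₓⱼ (SNP → exposure, log-OR per allele for a
binary liability) and β̂ᵧⱼ (SNP → outcome).  Under the instrumental-variable
assumptions each Wald ratio β̂ᵧⱼ/β̂ₓⱼ estimates the causal effect θ.

* **IVW.** θ̂ = Σwⱼβ̂ₓⱼβ̂ᵧⱼ / Σwⱼβ̂ₓⱼ², wⱼ = 1/se(β̂ᵧⱼ)² — the
  zero-intercept weighted regression of outcome on exposure effects.
  Fixed-effect SE 1/√(Σwⱼβ̂ₓⱼ²), inflated multiplicatively by
  √(Q/(k−1)) when Cochran's Q = Σwⱼ(β̂ᵧⱼ − θ̂β̂ₓⱼ)² exceeds its df
  (multiplicative random effects; overdispersion absorbs balanced
  pleiotropy).  With one instrument IVW reduces exactly to the Wald ratio.
* **MR-Egger.** The same weighted regression with a free intercept; the
  intercept estimates mean directional pleiotropy, the slope is
  consistent under InSIDE (instrument strength independent of direct
  effects).  SEs from the theoretical WLS covariance, inflated by
  max(1, √(Q_egger/(k−2))).
* **Weighted median.** Wald ratios sorted; the estimate interpolates
  where the normalized cumulative weight (wⱼ = β̂ₓⱼ²/se(β̂ᵧⱼ)², evaluated
  at each ratio's cumulative-weight midpoint) crosses ½.  Consistent when
  ≥ 50% of the weight is valid.  SE by seeded parametric bootstrap
  (default 1000 draws of β̂ₓⱼ, β̂ᵧⱼ from their sampling normals).
* **Mode-based estimators.** argmax of a normal-kernel density over the
  Wald ratios; bandwidth = φ · 0.9·min(sd, 1.4826·MAD)·k^(−1/5) with
  φ = 0.5; the weighted variant weights kernels by β̂ₓⱼ²/se(β̂ᵧⱼ)².  The
  argmax is located on a 10 000-point grid spanning the ratio range
  padded by three bandwidths; ties resolve to the smallest grid value.
  If all ratios coincide the common ratio is returned with SE 0 and a
  `degenerate` flag.  SE by the same parametric bootstrap.

**Diagnostics.** Mean F = mean(β̂ₓⱼ²/se(β̂ₓⱼ)²) for instrument strength
(the conventional exposure-SE form; > 10 indicates acceptable relative
bias).  I²GX = max(0, (Q_GX − (k−1))/Q_GX) measures how much
measurement error in β̂ₓ dilutes MR-Egger (> 0.9 desired); the weighted
variant takes Q_GX about the inverse-variance mean, the unweighted
variant about the plain mean with the mean squared SE as common variance.

**Scales.** For a binary-liability exposure all estimates are multiplied
by 0.693 (ln 2 at the conventional printed precision, kept at exactly
0.693 for comparability with published tables) to read as effect per
doubling of the exposure odds.  Log-odds outcomes may additionally be
exponentiated to odds ratios.  CIs are beta ± 1.96·SE on the estimation
scale and transform monotonically; Wald p-values never change under
these transformations.  The Egger intercept is a per-SNP direct effect
and is never put on the per-doubling scale.

## Harmonization

Records are matched on SNP id.  If the outcome's effect allele is the
exposure's other allele the outcome effect is sign-flipped and its
frequency complemented; strand-complement label pairs are complemented
first.  Palindromic variants (A/T, G/C) carry no strand information in
their labels: under the default `infer_by_eaf` policy they are aligned
by minor-allele matching when both frequencies fall outside the
ambiguity window [0.42, 0.58] and excluded inside it
(`drop_ambiguous` behaves identically here; `keep` trusts the labels).
Finally both studies are oriented so every β̂ₓⱼ > 0 (the
exposure-increasing allele convention).  Every decision is recorded in a
flags column and every exclusion in a reason map.

## Synthetic data

The generator gives every downstream stage a known truth.

* **Architecture.** Per seed: MAFs uniform on a configurable range
  (default 0.05–0.5), allele pairs from {A,C,G,T} with a configurable
  palindromic share (default 0.1), per-allele liability effects bⱼ with
  magnitudes 0.5 + |N(0,1)| (signed ±) rescaled so Σ2f(1−f)bⱼ² equals
  the exposure heritability h² (default 0.05, the order of variance
  explained by genome-wide-significant schizophrenia hits).  The
  magnitude floor emulates significance-selected instrument sets: every
  instrument's estimated sign is then reliable, which is what makes
  orientation to the exposure-increasing allele — and hence InSIDE —
  well defined.
* **Summary statistics.** β̂ₓⱼ = bⱼ + noise at se = 1/√(2f(1−f)N₁)
  (default N₁ = 145 000, a case-control GWAS scale); outcome effects
  θ·bⱼ + αⱼ + noise at N₂ = 300 000.  The pleiotropy αⱼ hits an
  `invalid_fraction` of SNPs, zero-mean (`balanced`) or with mean
  `pleiotropy_mean` (`directional`); α is defined relative to the
  exposure-increasing allele, as InSIDE is.  A configurable fraction of
  outcome records have swapped allele labels to exercise harmonization.
  Exposure and outcome noise use disjoint substreams (crc32-hashed
  stage names off one master seed), so the two samples never share
  estimation error.
* **Cohorts.** Dosages binomial(2, f); the genetic liability score g is
  the (b- or unit-weighted) dosage sum scaled to variance h²; full
  liability adds √(1−h²) Gaussian noise, and case status is assigned by
  threshold at a configurable prevalence (default 0.004 — the paper-scale
  study does not pin this number; it exists solely to exercise
  case-exclusion reruns).  Phenotypes apply a map m(g) — linear θ·g,
  quadratic θ·g + c·g², or cliff-edge θ·g + penalty·1[g > quantile] —
  plus small covariate effects (age, sex, one PC) and Gaussian noise;
  counts are rounded and floored at zero (Poisson optional).  Applying
  the map to the *genetic* score (noise added after) keeps group
  contrasts analytic: with a cliff at the 0.9 quantile and null slope,
  the top-decile mean sits below the 8th-decile mean by exactly the
  penalty in expectation.  It also makes the per-SNP outcome effect
  θ·bⱼ, so a cohort-derived outcome GWAS harmonized against the
  exposure summary recovers θ on the same scale as the pure
  summary-statistics route.
* **LD-score panels.** LD scores 1 + Gamma(2, ·) (right-skewed, mean 40);
  z-score pairs bivariate normal with E[z₁²] = 1 + N₁h₁²lⱼ/M and
  E[z₁z₂] = √(N₁N₂)·r_g·√(h₁²h₂²)·lⱼ/M, no overlap term.

What the generator does **not** emulate: LD between instruments (the
study design uses independent SNPs), imputation error beyond an info
column, assortative mating, participation bias, or real minor-allele
spectra.  Green tests therefore certify the *machinery* — estimator
algebra, calibration, power of the nonlinearity scans at these effect
sizes — not robustness to those real-data features.

## Outcome GWAS and filtering

Phenotype derivation follows the study's rules: childlessness = 1 iff
zero children; partner counts strictly above their empirical 99th
percentile set to missing; a top-decile partner indicator (≥ the
empirical 90th-percentile cut, reported alongside the cut used).
Associations are per-SNP complete-case regressions of outcome on dosage
with covariates (10 PCs always; age and sex for the outcomes measured in
both sexes), linear by closed-form OLS, logistic (for the binary
outcomes, so odds-ratio reporting is meaningful) via maximum likelihood;
p-values are two-sided Wald.  Variant filters: `flat` keeps
MAF > 0.01 and info > 0.8; `graded` applies the frequency-banded rule
(info > 0.3 above 3% MAF, > 0.6 for 1–3%, > 0.8 for 0.5–1%, > 0.9 for
0.1–0.5%, drop below 0.1%); records with missing info are dropped and
counted.  Sex is coded female = 0, male = 1 (affects intercepts only).

## Genetic-score sensitivity analyses

The score is an *unweighted* risk-allele count (mean-imputed missing
dosages, entirely-missing SNPs excluded with a warning); unweighted
because effect-size weights estimated in a mixed-sex GWAS would import
bias into sex-stratified analyses.  Quantile summaries use stable-rank
ties (equal bins ±1, half-open boundaries, lowest bin closed).  The
tail-removal scan drops the top f·n individuals by stable rank and
refits outcome ~ score + PCs for each f; n is strictly decreasing in f
by construction.  Quadratic fits center the score before squaring
(conditioning) and report raw-scale coefficients via the polynomial
identity; the vertex −b/(2a) carries a delta-method SE.

A design point worth recording: for a step cliff at the median of a
(near-)normal score, the expected scan slope is *not* monotone over the
whole 10–50% removal grid.  Writing c_f for the regression coefficient
of the penalty indicator in the sample truncated at the (1−f) quantile,
numeric evaluation gives c ≈ 0.470, 0.480, 0.437, 0.304, 0 at
f = 0.1…0.5: between the 10% and 20% removals the retained-sample
variance shrinks as fast as the covariance and the expected slope is
flat.  Power checks for "slope strengthens as the tail is removed"
therefore test the 20–50% fractions, with the cliff at the median so
every step strips part of the penalized group.  With the cliff at the
0.9 quantile only the first removal changes the estimand at all.

## LDSC-lite

Univariate: OLS of z² on the LD score; h² = slope·M/N, intercept
reported (1 + confounding).  Cross-trait: OLS of z₁z₂ on the LD score;
ρ_g = slope·M/√(N₁N₂), r_g = ρ_g/√(h₁²h₂²), intercept captures sample
overlap.  SEs by delete-one block jackknife over 200 contiguous blocks;
the cross-trait jackknife re-estimates all three regressions per block
so the r_g SE reflects heritability uncertainty.  Negative slopes and
|r_g| > 1 are flagged, never truncated — truncation would make
unbiasedness untestable.  The genome-wide method's iterative
heteroskedasticity weighting is deliberately omitted at synthetic scale;
real-data genetic correlations are out of scope (they need genome-wide
summary statistics and reference LD scores).

## Calibration experiments and problem sizes

The shipped experiments (test suite and `scripts/acceptance.py`) use:
200 replicates of 50-SNP instrument sets for estimator bias and IVW
coverage; the consistency check runs at an exposure GWAS of 2 000 000 so
instruments are effectively error-free — at the realistic F ≈ 35–90 of
the default configuration IVW shows its well-known ~1/F regression
dilution (a property checked separately: the bias shrinks as the
exposure sample grows).  Pleiotropy recovery uses mean α = 0.05,
sd 0.02 on all instruments.  Nonlinearity: 20 000-individual cohorts,
100 SNPs; 20 replicates for the scan, 100 smaller (n = 2000) replicates
for the null-calibration KS test.  LDSC: M = 20 000,
h² = 0.4/0.3, r_g = 0.5, N = 50 000.  These sizes keep a full run in
well under a minute per experiment while leaving Monte-Carlo error far
smaller than the effects tested.

## Known limitations

No SIMEX correction for Egger dilution, no MR-PRESSO/Steiger/
multivariable MR, no LD-proxy lookup, no real-PLINK input, no
mixed-model association.  Bootstrap SEs for median/mode estimators
assume normal sampling of the per-SNP effects.  The published per-SNP
instrument tables (electronic supplementary material of the source
study) are not redistributed here; the reproduction tests that consume
them report their absence rather than silently passing.
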