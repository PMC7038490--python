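# Methods

`cloudtongue` converts the quantitative output of an electronic tongue
(e-tongue) into a fuzzy, human-style evaluation sentence for Chinese
liquor. This note records the models, the defaults and why they were
chosen, and what the synthetic data generator does and does not emulate.

## The pipeline

An SA402B-class e-tongue reports 10 steady-state potentials per sample
(5 taste channels + 5 aftertaste channels, mV). The pipeline is:

1. **Flavor classification.** An RBF-kernel soft-margin SVM predicts the
   flavor (jiang, feng, nong, mild) from the raw 10-channel features.
   The penalty factor *c* and kernel width *g* are tuned by a genetic
   algorithm whose fitness is stratified k-fold cross-validation
   accuracy on the training set.
2. **Taste plane.** Centre-only PCA reduces the 10 channels to the first
   two principal components (PC1, PC2), reporting every component's
   variance contribution rate.
3. **Cloud model.** Each flavor's taste concept in the PC plane is a 2-D
   normal cloud with digital characteristics per axis: expected value
   Ex, entropy En and hyper-entropy He. The *backward* generator
   estimates them from training projections x₁..xₙ as

       Ex = x̄,   En = √(π/2)·(1/n)Σ|xᵢ − x̄|,   He = √(S² − En²),

   with S² the n−1 sample variance. The *forward* generator draws a
   droplet by sampling En′ ~ N(En, He²) per axis (conditioned positive),
   then x ~ N(Ex, En′²), with certainty degree
   μ = exp(−Σᵢ (xᵢ−Exᵢ)²/(2En′ᵢ²)).
4. **Word regions.** A 40-member sensory panel picks one description
   word per tasting from the flavor's five-word lexicon
   (GB/T 33405-2016). Sorting words by vote frequency n₁ ≥ … ≥ n₅ and
   cumulating, the i-th boundary multiplier is the standard-normal
   quantile kᵢ = Φ⁻¹(½ + cumᵢ/200); the word regions are the nested
   ellipses (x−Ex₁)²/(kᵢEn₁)² + (y−Ex₂)²/(kᵢEn₂)² ≤ 1, each word owning
   the annulus between consecutive boundaries. The outermost boundary is
   capped at k = 3 ("3En"), beyond which cloud mass is negligible.
5. **Evaluation.** For a new sample: predict the flavor, drop five
   forward-cloud droplets from that flavor's descriptor, locate each
   droplet's region, de-duplicate the words, order them centre →
   periphery, and emit "This liquor is w₁, w₂, …".

The contribution-rate integrals make the region construction
principled: the 1-D contribution of [a, b] is the Gaussian (sd = En)
mass of the interval, and the total 2-D contribution
∬ (2πEn₁En₂)⁻¹ exp(−½[(x−Ex₁)²/En₁² + (y−Ex₂)²/En₂²]) dx dy
normalizes to 1 (checked numerically to 1e-6).

## Parameters and defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| GA population / generations | 20 / 200 (pipeline uses ≤ 20) | search budget; on the synthetic data the optimum (100% CV) is reached within a few generations, so the pipeline's reduced cap loses nothing |
| c, g search range | [2⁻¹⁰, 2¹⁰] | log₂-scale encoding matches the range |
| GA operators | tournament (size 2), uniform crossover 0.7, Gaussian mutation σ = 0.5 in log₂ space at rate 0.1, elitism 1 | standard real-coded choices; elitism makes best-fitness monotone |
| CV folds | 5 | fitness of the GA |
| train fraction | 0.7 | the 14/6 per-flavor split |
| samples per flavor | 20 | replicate count per liquor |
| panel size | 40 | sensory panel membership |
| region cap | 3.0 | outer boundary in entropies |
| residual_sd | 1.3708 mV | see calibration below |

## Reference values and assumptions

The packaged descriptors (`data/table3_descriptors.json`) are the
published per-flavor (Ex, En, He) pairs per PC axis. The packaged
boundary multipliers (`data/region_multipliers.json`) are the published
per-flavor k sequences; they are carried separately because the
quantile formula above does **not** reproduce the published inner
multipliers (jiang n₁ = 50% gives k₁ = Φ⁻¹(0.75) ≈ 0.6745, while the
published geometry implies k₁ = 1.05) — only the k = 3 cap is
consistent. Both construction paths are first-class: the formula path
(`build_region_set`) is canonical, the explicit path
(`build_region_set_explicit`) reproduces the published geometry
bit-for-bit. No attempt is made to "fix" a second mismatch either: the
boundary quantiles are 1-D central-mass quantiles applied to a 2-D
ellipse, so the actual droplet coverage of the k-ellipse is
1 − exp(−k²/2) (elliptical Rayleigh law), not the nominal cumulative
frequency; the tests assert the true 2-D law.

Panel word frequencies: jiang is fully known (50/25/10/10/5% from votes
20/10/4/4/2 of 40). For the other flavors only anchors are known
(feng n₁ = 35%, n₅ = 5%; nong n₁ = 40%; mild n₁ = n₂ = 30%); the
remaining splits (feng 35/25/20/15/5, nong 40/25/15/10/10, mild
30/30/20/10/10) are package assumptions, config-overridable.

## The synthetic data generator

Real raw e-tongue tables for these liquors are not public, so the
generator emulates the *latent structure* rather than the instrument:
each flavor's 20 samples are drawn in the 2-D taste plane by the
forward cloud law of its reference descriptor, embedded into 10
channels via a fixed random orthonormal 10×2 loading (seeded QR of a
Gaussian matrix), offset by a fixed arbitrary mV vector (irrelevant
after centring), plus isotropic Gaussian noise of sd `residual_sd`
confined to the 8 orthogonal channel directions.

**Calibration.** `residual_sd = 1.3708` mV is fixed analytically so the
expected pooled covariance satisfies the reported two-component
cumulative contribution: 8·sd² = tr(C)·(1/0.9825 − 1), where
C = diag(mean(En² + He²)) + Cov(Ex across flavors) is the latent
mixture covariance. The descriptors fix the latent eigenvalue ratio, so
PC1's expected share comes out 0.940 (reported: 0.9424) — both
components land inside a ±0.02 band but cannot be matched exactly
simultaneously.

**What it does not emulate:** sensor drift, cleaning cycles, dilution
chemistry, the 30-s transient before the steady state, inter-channel
correlation of the residual noise, and panel behaviour beyond a
multinomial vote. Passing tests therefore demonstrate that the pipeline
recovers the structure it assumes, not that a physical instrument obeys
that structure.

**Cluster overlap is real.** With the reference He values the jiang and
nong clouds genuinely overlap; roughly half of fully re-randomized
datasets contain a tail sample inside the other flavor's cluster, in
which case even an exhaustively tuned SVM cannot reach 100% held-out
accuracy. The documented demonstration condition (dataset seed 1,
split seed 1) is separable; the GA then reaches 100% test accuracy for
every search seed tried.

## Numerical choices

- Backward cloud: S² uses the n−1 divisor; when S² < En² (common at
  n = 14–20) He is clamped to 0 with a warning rather than erroring.
- Forward cloud: negative En′ draws are resampled, preserving the
  normal law conditioned on positivity. This biases the backward En
  estimate upward by He·φ(En/He)/Φ(En/He) under a round trip — up to
  ≈ 11% where He/En ≈ 0.7 — which is a property of the first-order
  backward estimator, not of the implementation; round-trip consistency
  is therefore asserted exactly in the He = 0 case and against the
  biased-expectation oracle when He > 0.
- PCA loadings: sign fixed so each column's largest-magnitude entry is
  positive; covariance divisor n−1; channels are centred, never scaled
  (they share mV units).
- Region boundaries: boundary points belong to the inner region (≤
  inner, > outer). Zero-frequency words yield zero-width annuli: the
  word is retained in the region list but can never be selected.
- Droplets beyond the k = 3 cap (probability e⁻⁴·⁵ ≈ 1.1% per droplet
  at He = 0, more with He > 0) take the outermost word by default so an
  evaluation always has exactly 5 located droplets; a `resample` policy
  redraws them instead.
- Integrals use adaptive quadrature (`scipy.integrate`); the 2-D
  normalization integrates over a ±8·En box (truncation error ≪ 1e-6).
- Degenerate inputs: constant samples give (Ex, 0, 0); En = 0 is
  rejected wherever a density or region needs spread; a single flavor
  class aborts the pipeline with a clear message.

## Problem sizes used

Unit tests run Monte-Carlo checks at n = 2·10⁴ and the consistency /
coverage checks at n = 10⁵; the pipeline demonstrations use the default
4 × 20 dataset with a GA budget of population 20 and ≤ 20 generations —
sizes chosen so the whole suite runs in seconds while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The published inner multipliers cannot be derived from the stated
  quantile construction (above); users reproducing the published
  geometry must use the explicit path.
- The kernel is the standard RBF exp(−g‖x−y‖²); one printed form of the
  kernel reads exp(−g‖x−y‖)², which we interpret as a typesetting
  artefact.
- Word frequencies for three of four flavors are partly assumed.
- The backward-cloud He estimate is noisy at n = 14 training samples
  per flavor (often clamped to 0); the evaluation sentences are robust
  to this because regions depend only on (Ex, En).
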