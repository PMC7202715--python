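# Methods

This note documents the models, parameter choices and numerical conventions
behind `eacmap`, and what the synthetic cohort does and does not establish
about real recordings.

## Forward model and estimator

The head is treated as a semi-infinite homogeneous diffusive medium with zero
boundary conditions: CW reflectance at source–detector distance r is
`I(r) = A·exp(−μ_eff·r)/r²` with `μ_eff = sqrt(3 μ_a (μ_a + μ_s′))`.  The
generator uses exactly this solution (no extrapolated-boundary refinement),
deliberately: the estimator's own model must be the generator's model for
parameter-recovery tests to be meaningful.  No Monte-Carlo photon transport,
layered or voxelized head models, or frequency-domain phase are simulated.

With Poisson counting statistics the variance of the block-normalized signal
is 1/N̄ (N̄ = mean counts), so `SNR² = 1/var(i/i_avg) ≈ N̄ ∝ I` and
`y = ln(SNR² r²)` is linear in r with slope −μ_eff.  The estimator is plain
unweighted OLS of y on r; neighbourhood (30 mm radius, chord metric on
channel midpoints, boundary inclusive), global (all accepted channels) and
distance-bin variants differ only in the channel subset.  Guards: a fit
needs ≥ 5 channels spanning ≥ 10 mm (≥ 5 mm inside a 10 mm distance bin);
per-channel failures become missing values with a reason code, never
exceptions, so cohort runs do not abort on a bad channel.  The default
channel window is 20–50 mm inclusive — below 20 mm the log-linearity
assumption fails even in homogeneous media, above 50 mm the SNR flattens —
while the distance-stratified analysis uses the wider 15–25/25–35/35–45/
45–55 mm bins.

Zero-phase (forward–backward) order-4 Butterworth filters are used for the
10 Hz high-pass and the cardiac band-pass.  The high-pass removes the
sub-10 Hz physiological band whose variance is not shot noise; it also
multiplies the white shot-noise variance by a fixed band fraction, which is
identical for every channel and therefore shifts only the intercept k, never
the slope.  Processing order is fixed: normalize → movement-correct →
high-pass → SNR.  Movement correction is robust-z spike interpolation
(running median over ~1 s, MAD scale, threshold 5; > 10% replaced flags the
channel, > 50% rejects it) — synthetic data are clean, so this is a
defensible hook rather than a tuned artifact model.  The robust scale is
floored at the shot-noise SD implied by the channel's mean counts: on dim
channels the discrete Poisson counts collapse the MAD and every photon
would otherwise register as a spike.
Multi-block recordings are averaged per channel in y (log domain) before
fitting.

### The estimand under an inhomogeneous field

The generator imposes a smooth opacity relief (below), so "the" global EAC
of a subject is a weighted average of the local field.  The expected OLS
slope over channels c is `Σ w_c μ_c / Σ w_c` with leverage weights
`w_c = (r_c − r̄)·r_c`; the ground-truth table stores both the base
(spatial-mean) μ_eff and this leverage-weighted channel average
(`eac_*_global_truth`), and recovery is judged against the latter because it
is what the slope estimator targets.

## Synthetic cohort

The generator's defaults are the study conditions of the aging cohort the
package emulates, not free dials:

- 48 subjects, ages uniform over 18–78, 8 per decade, sexes balanced 4/4
  per decade; sampling 39.0625 Hz; four consecutive helmet placements per
  subject, each with 64 paired-wavelength source positions and 24 detectors
  (384 channels/placement, 1536 per session, distances 15–80 mm on a
  90 mm spherical cap, optodes within 100° of the vertex).
- Channel counts are Poisson around the diffusion forward model, modulated
  multiplicatively by global cardiac (1.1 Hz, 2%), respiratory (0.25 Hz,
  1%) and drift (0.02 Hz, 0.5%) sinusoids, all far below the 10 Hz
  high-pass.  The photon budget — 2·10⁵ expected counts/sample at a 20 mm
  reference channel — puts the 20–50 mm window in the regime where shot
  noise dominates but long channels become genuinely dim (tens of counts),
  as in practice; channels below 1 expected count/sample are flagged
  low-light.  Block duration defaults to 30 s, the package's standard
  cohort-study condition (a single block already yields ~1% slope
  precision; the variance estimator's error scales as sqrt(2/n_samples)).
- Per-optode gains are log-normal with σ = 0.5 — an order-of-magnitude
  spread emulating heterogeneous source powers, detector sensitivities and
  scalp coupling.  Gains are redrawn per subject and per placement.
- Latent physiology: SO₂ ~ 0.65 ± 0.04 declining weakly with age (target
  r = −0.31); total hemoglobin 70 μM (log-SD 0.08); μ_s′ around
  0.83/0.72 mm⁻¹ at 690/830 nm (standard adult-head values).  Absorption
  follows `μ_a = ln10·(ε_HbO·SO₂ + ε_HbR·(1−SO₂))·tHb` with Prahl/Cope
  extinction coefficients (690 nm: 276/2051.96; 830 nm: 974/693.04
  cm⁻¹ M⁻¹), recorded in the config JSON for provenance.
- Cortical thickness is linear in age (target r = −0.65) plus Gaussian
  noise; a log-linear link scales each subject's (μ_a, μ_s′) jointly with
  thickness (coupling 0.17 in ln μ_eff per SD of thickness) — thinner
  cortex → thicker clear CSF layer → lower whole-head EAC.  The coupling
  strength is chosen so the cohort's age–EAC1 correlation sits at the
  study's anchor (≈ −0.49); because the generator routes the entire age
  effect through thickness (a pure chain, which the mediation analysis
  should call "full"), the thickness–EAC1 correlation comes out somewhat
  stronger (~0.8) than the observational value (~0.58), which in real data
  is diluted by EAC variance from sources unrelated to thickness
  measurement.  This is the one place the generator trades table-level
  fidelity for a clean causal structure.

### Calibration

Two solvers turn the cohort targets (EAC means 0.192/0.170 mm⁻¹, SDs
0.040/0.036 mm⁻¹, cross-wavelength r = 0.85, age–thickness r = −0.65,
age–SO₂ r = −0.31) into generator parameters:

1. **Dispersion** (closed form, log space): the SO₂ slopes
   d ln EAC/d SO₂ are computed by finite differences at the latent means;
   the target covariance is decomposed into SO₂, total-hemoglobin, common-
   scattering and anatomical shares, and the residual per-wavelength
   variance is assigned to wavelength-specific scattering.  Any negative
   allocation raises `CalibrationError` (e.g. a cross-wavelength r too
   high for the requested SDs).
2. **Means** (fixed point): a deterministic internal Monte-Carlo sample
   (hard-coded seed, 16384 draws, independent of the user seed) iterates a
   common scale (through tHb) and per-wavelength scattering scales until
   the expected EAC means equal the targets; convergence is geometric
   because EAC is homogeneous of degree 1 in (μ_a, μ_s′) and ~degree ½ in
   μ_s′ alone.

All per-run randomness flows from the master seed through spawned
`SeedSequence` streams (montage, ages, subjects, gains, time series), so
identical configs give identical cohorts; raw blocks are simulated lazily
from per-subject child seeds rather than materialized (a 48-subject session
held in memory would be ~0.8 GB).

### Topographic relief

Real heads are not spatially homogeneous: dorsal/occipital scalp is
markedly more opaque than frontal/lateral regions.  The generator therefore
modulates the local μ_eff by a fixed smooth pattern on the sphere
(`cosθ` toward the vertex plus a posterior term, normalized to zero mean /
unit SD over the cap, ln-amplitude 0.10 ⇒ roughly ±20% range, comparable to
the ~40% min-to-max spread reported for real maps).  The same pattern at
both wavelengths is what makes split-half reliability and cross-wavelength
map correlation meaningful — on a homogeneous head, group mean maps would
have no pixel variance to correlate.  Consequences: the map-level
reliabilities on synthetic data (~0.97) probe the analysis chain, not the
anatomy; real-data reliability additionally reflects vasculature and
optode-placement variability that the generator does not model.

## Mapping

Channel midpoints are flattened by the azimuthal-equidistant projection
about the vertex (ρ = θ/θ_max with θ_max = 100°, azimuth preserved; points
beyond θ_max are clipped to the rim and flagged) — the standard circular
scalp template; it is invertible for unclipped points and mildly distorts
ventral locations.  Interpolation is piecewise-linear on the Delaunay
triangulation of the projected channels over a 64×64 disk raster, with
nearest-neighbour fill (flagged "extrapolated") between the convex hull and
the rim.  Group maps report the per-pixel mean and SE% = 100·(SD/√n)/mean;
correlations use jointly valid pixels only; the split-half split is
stratified by (age decade, sex).  Because the warp and kernel are package
conventions, synthetic map values are comparable across analyses in
*pattern*, not pixel-for-pixel against any external map.

Local component maps apply the cohort-level (global) PC loadings to each
pixel's centred (EAC₆₉₀, EAC₈₃₀) pair.  Global loadings were chosen over
per-pixel loadings for identifiability: per-pixel eigenvectors have
pixel-dependent sign/rotation ambiguities that make across-pixel comparison
of "EAC1" ill-defined.

## Oxygenation and wavelength PCA

The TOI inversion assumes a scattering power law
μ_s′(λ) = μ_s′(830)·(λ/830)^(−b) with b = 1 and μ_s′(830) = 0.72 mm⁻¹ by
default, inverts the exact EAC closed form per wavelength for μ_a (positive
root of the quadratic), and unmixes the two absorptions into HbO₂/HbR
through the packaged extinction matrix; TOI = C_HbO/(C_HbO+C_HbR).  Negative
concentrations (possible for out-of-gamut EAC ratios) are clamped to zero
and flagged non-physical.  A `ratio` mode replaces the exact root by
μ_a ≈ EAC²/(3μ_s′), under which the TOI depends on the EAC pair only
through their ratio; the two modes agree within ~2% over the in-range EAC
values.  The inversion is exact (≤1e-10) whenever its scattering
assumptions match the forward generator; on the default cohort the drawn
μ_s′ values deviate from the power law, so cohort TOIs carry a bias — the
analyses use TOI's correlation structure, which survives.

Wavelength PCA eigendecomposes the 2×2 **covariance** (not correlation)
matrix of the per-subject EAC pairs — the variables share units and their
unequal SDs are informative.  Signs are fixed so PC1 has two positive
loadings (the anatomical "average" axis) and PC2 a positive 690 nm loading
(the oxygenation "difference" axis); ties are broken by wavelength order.
Scores are centred-data projections; loadings·scores + mean reconstructs
the input exactly.

## Statistics

Correlations report Pearson r, Fisher z = atanh(r) with SE = (N−3)^(−1/2),
and two-sided t-based p-values (df = n−2; partial correlations residualize
both variables on the covariate with intercept and use df = n−3).  |r| = 1
yields a flagged infinite z rather than an exception.  No multiple-
comparison correction is applied anywhere, matching the analysis battery
this package reproduces; significance tiers are 0.05 and 0.10.  Sex is
coded 1 = M, 2 = F.

Composite cognitive scores z-standardize each raw test across subjects
(sample SD), flip timed tests so positive = better than average, and
average the oriented z-scores within the "performance" (Raven's, digit
spans, O-Span, Trails A/B/B−A) and "verbal" (Shipley vocabulary, fluency)
domains with equal weights; zero-variance tests are excluded with a warning.

Mediation follows the three-step Baron–Kenny scheme on standardized
variables (a raw-coefficient option exists): step 1 Y~X (total effect c),
step 2 M~X (path a) — either non-significant at α = 0.05 ⇒
"not-assessable"; step 3 Y~X+M gives the direct effect β₁ and mediator
effect β₂.  "Full" = β₁ non-significant and β₂ significant; "partial" =
β₁ significant but attenuated (|β₁| < |c|) **and** Sobel significant — the
Sobel requirement operationalizes "significantly reduced but still
present" as a testable criterion; otherwise "none".  The Sobel statistic
is a·b/√(b²SE_a² + a²SE_b²), reported with both normal- and t-referenced
(df = n−3) p-values.  The classification is invariant to affine rescaling
of X, M, Y.

## Problem sizes and known limitations

- The standard cohort run (48 subjects × 4 placements × 30 s blocks)
  simulates ~2.2·10⁸ Poisson samples and completes in a few minutes on one
  CPU; the mediation replicate study uses latent cohorts only (the chain
  being tested lives in the latent layer, and estimation noise is ~1–2%
  against component SDs of ~20%).
- The spherical-cap montage is a stand-in for the real (unpublished)
  helmet geometry; neighbourhood sizes (~20–35 channels at 30 mm) therefore
  differ from the ~19 of the original arrays and are treated as context,
  not a target.
- Estimator and generator share the forward model by design; accuracy
  figures quantify noise propagation, not model misspecification.
- HR/HRV extraction detects diastolic troughs on the band-passed pooled
  pulse with a spectrum-adaptive refractory period and parabolic sub-sample
  refinement; it is validated on synthetic pulse trains, not against EKG.
- The TOI is a two-wavelength method: water/lipid chromophores and >2
  wavelengths are out of scope, and no 3D tomographic EAC reconstruction is
  attempted (the multi-distance estimator is intrinsically low-resolution).
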