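# eacmap

Estimation and analysis of the optical **Effective Attenuation Coefficient
(EAC)** from multi-distance continuous-wave near-infrared (CW-NIRS)
recordings of the adult head — the opacity measure whose cohort-level
structure tracks cortical atrophy and brain tissue oxygenation in aging.

It is written for researchers in diffuse optical imaging who want to (a)
estimate absolute EAC maps from uncalibrated CW intensity data recorded with
a high-density, multi-distance optode montage, and (b) study what those maps
say about brain health — without access to the original (non-public) human
cohort.  A first-class synthetic-cohort generator reproduces the study
conditions end to end, so every stage is testable from a seed.

## The model

In a semi-infinite homogeneous diffusive medium, CW reflectance decays with
source–detector distance r as `I(r) ∝ exp(−μ_eff·r)/r²`, where

```
μ_eff = sqrt(3 μ_a (μ_a + μ_s′)) ≈ sqrt(3 μ_a μ_s′)        [mm⁻¹]
```

is the EAC (μ_a absorption, μ_s′ reduced scattering).  With shot-noise-
dominated counts, `SNR² ∝ I`, so

```
ln(SNR(r)² r²) = k − μ_eff · r
```

and the EAC is the negative slope of a straight-line fit over channels at
many distances; the intercept k absorbs source power, detector efficiency
and fiber coupling.  The package implements:

- **synthetic cohort** — spherical-cap montages (paired 690/830 nm sources,
  log-normal optode gains), latent subjects whose μ_a/μ_s′ follow age,
  cortical thickness and oxygen saturation, Poisson channel counts with
  sub-10 Hz physiological modulation at 39.0625 Hz, and a dorsal/occipital
  opacity relief;
- **preprocessing** — block normalization, robust-z movement correction,
  zero-phase 10 Hz Butterworth high-pass, the SNR table, and heart-rate /
  HRV extraction from the optical pulse;
- **EAC estimation** — global, neighbourhood (30 mm) and distance-stratified
  slope fits over the 20–50 mm channel window;
- **topographic mapping** — azimuthal-equidistant projection to the circular
  head template, linear interpolation onto a disk raster, group mean and
  SE% maps, split-half reliability, map correlations;
- **spectral oxygenation** — a two-wavelength Tissue Oxygenation Index
  (power-law scattering assumption, exact inversion of the EAC closed form,
  hemoglobin unmixing), and PCA of the per-subject (EAC₆₉₀, EAC₈₃₀) pairs
  into anatomical (EAC1) and oxygenation (EAC2) components;
- **association statistics** — composite neuropsychological scores, Pearson
  and age-partialed correlations with Fisher z (SE = (N−3)^(−1/2)), paired
  t-tests, and Baron–Kenny mediation with the Sobel test.

## A worked example

```python
>>> import eacmap as em
>>> em.mu_eff_from_coefficients(0.0144, 0.830, mode="approximate")
0.18936...
```

Literature adult-head coefficients at 690 nm (μ_a = 0.0144 mm⁻¹,
μ_s′ = 0.830 mm⁻¹) give an EAC of **0.189 mm⁻¹** — squarely inside the
0.192 ± 0.040 mm⁻¹ cohort distribution the generator is calibrated to.

Running the whole study (`examples/06_full_pipeline.py` uses 12 subjects;
the full configuration is `SimulationConfig()` with 48):

```
$ python examples/06_full_pipeline.py
pipeline on 12 subjects (67 s: ...)
global EAC (mm^-1): 690 nm 0.183 +/- 0.036, 830 nm 0.158 +/- 0.032
per-subject recovery vs generator truth: worst 2.6%
split-half map reliability: 690 nm r = 0.916, 830 nm r = 0.851
cross-wavelength map correlation r = 0.968
PC1 share of wavelength-space variance: 96.0%
mediation (age -> EAC1 via thickness): not-assessable
```

i.e. the estimator recovers each subject's opacity to a few percent under
realistic shot noise and order-of-magnitude gain heterogeneity, group maps
are reliable even at n = 12, and the wavelength space splits into an
anatomical axis and an oxygenation axis.  (At n = 12 the age–EAC1
correlation is not yet significant, so the mediation chain is not
assessable; the 48-subject configuration classifies it "full" in the large
majority of seeds — see `examples/05_association_and_mediation.py` and the
acceptance script.)

The other example scripts each demonstrate one capability: forward model and
estimator (`01`), raw simulation and preprocessing (`02`), topographic maps
(`03`), oxygenation and PCA (`04`), the statistics battery (`05`).

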