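# Methods

This note records the models, parameter choices and numerical conventions
behind `inkdose`, and what the synthetic experiments do and do not show.

## Measurement model

A push-broom NIR-HSI sensor acquires one spatial line (320 px across a 38 mm
field of view, 0.114 mm/px) times 930–1700 nm per frame; the second spatial
axis comes from stage motion (200 µm/s at 111 frames/s, i.e. a raw
along-track pitch of v/f ≈ 1.8 µm). Cubes are indexed
`(frame, spatial_px, wavelength)`. Reflectance counts S convert to
absorbance against white (W) and black (D) references as
`A = −log₁₀((S−D)/(W−D))`, the ratio floored at 1e-6 so dead pixels stay
finite; the clipped-pixel count is recorded in cube metadata. References are
stored per spatial pixel; a single mean spectrum is broadcast.

### Resolution

The motion-direction PSF is modelled as Gaussian. A printed reference line
(width `b_line`, assumed to contain 6σ of its own Gaussian because of its
steep edges) convolved with the PSF gives the measured transit, so
`σ_PSF = √(σ²_meas − σ²_line)`. `σ_meas` comes from the *counted* number of
frames at or above half maximum (no sub-pixel interpolation; an
interpolating variant exists behind a flag for validation). The
frame-to-length factor `k` is always an explicit input: the instrument's
documented k = 20 µm/px does not equal v/f at the documented stage settings,
and the package deliberately refuses to resolve that ambiguity silently.
Baseline is the median of the first and last 10% of the transit; polarity
(dark line on bright background or the reverse) is auto-detected.

Forward validation samples the peak midway between two frames (phase 0.5),
the least biased alignment for an integer count; recovery is then within
half a pixel scale for PSFs from 50 to 300 µm.

### Pretreatment

Default chain, in order: restrict to 1200–1600 nm → SNV → Savitzky-Golay
derivative (order 2, window 35 points, first derivative, abscissa step = the
grid's mean wavelength step). Rationale for the order: SNV statistics are
then confined to the modelled window. SNV uses the n−1 standard deviation.
The derivative order is a configuration default (first), recorded in the
model's preprocess card; the card travels with every preprocessed cube and
prediction refuses cubes whose card does not match the model's. The
Savitzky-Golay edge policy fits the same-order polynomial over the terminal
full window and evaluates it at the edge abscissae — no reflection padding,
so no fabricated data enters the model.

### Calibration

The absolute dose scale comes from per-spot reference masses (an external
HPLC-like assay, simulated with 1% multiplicative error and a 5 µg
quantification limit; spots below 50 drops fall under it and are excluded).
Raman band maps (730–740 cm⁻¹ trapezoidal integrals above a linear
endpoint-to-endpoint baseline) provide only the *within-spot* distribution:
pixels receive concentrations proportional to their stratum's mean band
integral, rescaled so each spot's pixel masses sum exactly to its reference
mass (mass closure, enforced to machine precision).

Stratification granularity is the key free choice. `stratify_response`
defaults to 3 quantile strata (centre/annulus/rim) with non-negative
weights. The end-to-end pipeline instead uses the fine-stratification limit
(per-pixel proportional allocation) with *signed* band integrals, for two
measured reasons:

* coarse strata coarsen the response to its stratum mean, and a linear
  model fitted to coarsened responses regresses toward those means
  (attenuation ≈ between-stratum/total variance, ≈ 0.82 for 3 strata on a
  Gaussian deposit); the lost slope reappears as a positive intercept that
  grossly inflates predictions at the low densities of thin test patterns;
* flooring noisy band integrals at zero before closure rescaling rectifies
  zero-mean Raman noise into rim mass — at realistic Raman SNR this steals
  about a third of a 50-drop spot's mass into random rim pixels and
  flattens the calibration. Signed per-pixel weights keep the allocation
  unbiased; individual pixel responses then carry noise (occasionally
  negative), which regression handles, while spot totals stay exact.

Training rows are the mapped spot pixels of all retained spots plus ~400
blank substrate pixels (y = 0) sampled away from any spot, anchoring the
calibration at zero concentration. X and y are mean-centred; no variance
scaling (spectra are already SNV-treated).

SIMPLS (de Jong) is implemented directly: successive weight vectors from
the deflated cross-product vector, deflation against an orthonormalised
loading basis (double Gram-Schmidt passes keep scores orthonormal to
~1e-14 over 20 components), unit-norm scores, and
`β_slope = R q` so that `ŷ = ȳ + (x − x̄)·β_slope`. The rank guard is
relative to the first component's score norm (1e-12): noiseless synthetic
spectra after SNV span exactly two directions (substrate and API), so the
pipeline caps the requested 5 components at the achievable rank in that
limit. Venetian-blind cross-validation (systematic fold assignment, seeded
offset) reports RMSECV per candidate component count; on the synthetic
strip the RMSECV curve is flat beyond ~3 components and the pipeline keeps
the study's choice of 5.

### Prediction and dose

Per-pixel `ŷ = ȳ + (x − x̄)·β`; negative predictions are floored at zero in
the map with the floored fraction logged and the unfloored layer kept for
diagnostics. Doses are sums of map values over a printed-region mask —
either a fixed-geometry mask from the known pattern (simulation tests;
threshold 1e-4 of the true pixel-mass peak, capturing ≥ 99.9% of deposited
mass) or Otsu thresholding of the 1515 nm absorbance image with small
components removed. Dose integration is additive over disjoint masks.
Printer doses are `n_drops × 415 pl × 250 mg/ml`; comparisons report
per-pattern bias (%) against reference and printer plus replicate RSD
(100·sd/mean, n−1).

`mixing_coefficient` has units AU·mm²/mg and multiplies areal density
(pixel mass / pixel footprint), not raw per-pixel mass: the optical response
of a deposit must not depend on the stage speed used to sample it.

## Synthetic study conditions

The generator reproduces the study's printed layouts and instrument
geometry; where the physical chain is undocumented, values were chosen once
for realism and frozen:

| parameter | value | basis |
|---|---|---|
| drop volume / ink | 415 ± 5 pl, 250 mg/ml | printer characterisation |
| calibration strip | 9 spots, 10–500 drops, 3.2 mm pitch | printed layout |
| test squares | 17×17 drops at 300 µm, 1–10 layers | printed layout |
| single-drop footprint | Gaussian σ 150 µm, centre-excess 2 | drop ~0.3 mm scale; Raman maps show centre-high deposits |
| spot spreading | σ ∝ (N/10)^0.25 | N-drop puddles spread sub-linearly; spot diameters grow along the strip |
| PSF | Gaussian σ 154 µm | the resolution analysis |
| across-track pitch | 114 µm/px | sensor field of view |
| along-track sampling | 200 µm/s at 111 fps, 28 frames co-added → ≈50 µm working pitch | see below |
| wavelength grid | 930–1700 nm, 5 nm steps (155 bands) | desk-scale spectral sampling |
| endmembers | structured substrate baseline (water band at 1450 nm); API band at 1515 nm + minor band | substrate/API spectra |
| mixing coefficient | 3 AU·mm²/mg (max calibration absorbance ≈ 0.26 AU) | reflectance-mode NIR signal scales |
| detector noise | 1% of background-subtracted counts per raw frame | typical line-scan SNR |
| scatter | per-pixel multiplicative, U(0.97, 1.03) | SNV's target artefact |
| Raman | Lorentzian at 735 cm⁻¹ (HWHM 6 cm⁻¹), area 1e6 counts·cm⁻¹/mg, 1-count noise, 3 scans, sampling footprint σ 150 µm | band SNR ~5–20 at spot pixels, plausible for 6 s maps |
| reference assay | 1% multiplicative error, 5 µg LOQ | quantification-limit behaviour |

Frame co-adding deserves a note: at the instrument's raw 1.8 µm pitch every
50 µm of sample is seen by ~28 frames, so any working grid at that scale
inherits a √28 noise averaging. The desk-scale cubes therefore keep the
true stage and frame settings and co-add 28 frames per stored line rather
than pretending a faster stage. Deposition rasters are 10 µm cells, finer
than both the PSF and the pixel pitch; drop kernels are normalised
discretely so deposited, blurred and pixel-resampled fields all integrate
to the same total to better than 1e-9 (blur margins keep all sources beyond
the truncated filter support).

Problem sizes for the end-to-end experiments — one strip (~600×43×155
cube), four squares (~190×85×155 each), ten seeds per noise condition —
keep a full calibration-plus-prediction cycle at a few seconds.

## What the synthetic experiments show — and what they don't

Passing recovery tests shows the chain is *self-consistent*: with linear
mixing, Gaussian blur, multiplicative scatter and the stated noise levels,
calibration transfers from spread spots to layered squares within 5%
(noiseless) and 15% (1% noise) on dose totals, and predicted dose is
monotone in layer count. Real measurements add effects the generator
deliberately omits: sampling-depth attenuation in thick multilayer deposits
(the generator is strictly linear in mass; an optional extra blur for ink
migration exists but is off by default), substrate heterogeneity and
water-content drift, wavelength-dependent scatter, detector nonlinearity
and dead pixels, and a Raman-vs-NIR registration error. Results on real
cubes will be correspondingly worse, particularly at high layer counts.

## Numerical conventions and degenerate inputs

* Wavelength selection is inclusive on both edges; nearest-wavelength
  lookup breaks ties toward the lower wavelength.
* All pixel ranges are 0-based half-open; axis 0 is stage travel.
* SNV of a constant spectrum, FWHM of a flat profile, dose over an empty
  mask, and deconvolution with `σ_meas ≤ σ_line` raise typed errors; an
  all-background mask image warns and returns an empty mask.
* Quantile-stratum boundary ties go to the lower stratum.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence.spawn`; repeated runs are
  bit-identical.
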