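# Methods

This note documents the models, estimators and numerical choices behind
`octdent`, and what the synthetic phantoms do and do not establish.

## SD-OCT reconstruction (`octdent.recon`)

A spectral-domain OCT camera records, per A-line, the interference spectrum
on a grid uniform in wavelength.  Reconstruction inverts this record:

1. **DC removal** — subtract the reference-arm spectrum when recorded,
   otherwise the mean spectrum across A-lines.  Output fringes are zero-mean
   per spectral channel.
2. **k-linearization** — cubic-spline resampling from uniform λ to a uniform
   wavenumber grid k = 2π/λ of the same length and span.  Without it the
   fringe of a single reflector is chirped and the FFT peak smears.
3. **Windowing** — Hann by default (sidelobe suppression for imaging);
   `none` for resolution metrology, where apodization would broaden the PSF.
4. **Dispersion compensation** — the analytic signal (Hilbert transform
   along k) is multiplied by exp(−i(a₂(k−k₀)² + a₃(k−k₀)³)).  Sign
   convention: the compensation phase is the negative of the phase a frame
   was synthesized with, so passing the synthesis coefficients undoes them.
   `"auto"` grid-searches (a₂, a₃) maximizing Σ I^1.3 (a standard
   derivative-free sharpness metric, monotone under energy-preserving
   phase-only changes), coarse-to-fine over three levels — deterministic.
5. **FFT** — magnitude squared of the positive-frequency half, linear
   intensity.  For cos(2kz) sampled on N uniform k points with pitch dk,
   bin m maps to z = mπ/(N dk); the axial pitch in air follows from the
   k-span (1.476 µm for 2048 samples over 675–875 nm).  FWHM measurements
   zero-pad ×4 and interpolate linearly between samples.

**Axial resolution convention.**  `axial_resolution()` quotes the FWHM of
the *modulus* (amplitude) A-scan.  Under this convention a Gaussian source
of center λ₀ and power-spectrum FWHM Δλ gives the coherence-length limit
(2 ln2/π)·λ₀²/Δλ (2.52 µm at 775/105 nm).  The intensity (magnitude-squared)
profile is narrower by √2 and is what `reconstruct()` returns for imaging.
At the instrument's 675–875 nm span the Gaussian is truncated at ±2.2σ,
which broadens the measured FWHM by ≈4 % to 2.62 µm — the value a real
spectrometer of this design reports (≈2.6 µm).  The closed form is exact
only when the source is sampled far into its tails; tests verify it with a
575–975 nm sampling of the same source.

In-tissue lengths divide by the group index (enamel 1.6, so 2.6 µm in air →
1.63 µm in enamel).  USAF-1951 bar width: 500/2^(g+(e−1)/6) µm.

## Surface roughness (`octdent.surface`)

Rq is the RMS of the surface-height residual after the tooth's macroscopic
form (waviness) is removed:

    Rq = sqrt( (1/n) Σ z_i² ),   z_i = height_i − waviness_i,

computed per B-scan over unmasked A-scans (≥10 required).  Heights are on
the in-air optical scale — roughness is a property of the air–enamel
boundary, above the tissue.

**Surface detection.**  The B-scan is averaged over 3 neighboring A-scans
(speckle is independent per voxel while the surface is correlated over the
roughness correlation length, so a short lateral average buys localization
precision at a small, quantifiable cost in lateral bandwidth), median
filtered over 3 depth samples, and thresholded at
floor mean + 6 × floor SD (floor statistics from the first 8 depth
samples; a small floor proportional to the image maximum guards the exactly
noise-free case).  A crossing must be sustained for 3 consecutive samples —
isolated exponential-noise spikes survive a median filter in pairs often
enough to matter otherwise.  The position is refined to sub-pixel by an
intensity centroid over a 5-px window centered on the specular interface
line (distinguished from a step edge by whether the profile decays after its
maximum).  A 3-px lateral median despikes the height profile.  With fully
developed speckle this chain localizes the surface to ≈0.4 px mean absolute
error at 1.5 µm/px.

**Waviness removal.**  Grayscale morphology with a flat structuring element
of fixed physical length (default 70 µm, converted to an odd pixel count,
edge replication at the boundaries).  The two single-scale compositions
close(open(f)) and open(close(f)) are biased toward the lower/upper envelope
respectively; their average (the default) is odd-symmetric — filtering −f
yields −waviness — and unbiased for sign-symmetric roughness.  Two intrinsic
flat-element error floors are worth knowing: an outer opening clips smooth
crests by A(1 − cos(π·SE/P)) for waviness of amplitude A and period P (hence
the guidance that waviness periods be ≥5× the element), and a bright spike
of width w on a slope s leaks by ≈ s·w into any composition.  For one-sided
artifacts the `open-close` branch is available and preferable.

**Summary statistics.**  Mean, sample SD and a Student-t 95 % CI across
B-scans; a single B-scan yields an undefined (NaN) CI rather than a guess.

## Scattering coefficient (`octdent.scatter`)

Below the surface the single-scattered OCT intensity is modeled as

    I(z) = I0 · exp(−2 µs z) · 1/(1 + ((z − z_f)/z_R)²),

Beer–Lambert attenuation (round trip, hence the 2) times the Lorentzian
confocal factor of a focused beam with focal depth z_f and Rayleigh length
z_R.  z is geometric depth below the *detected* surface: optical depth
divided by the enamel group index (1.6), in mm inside the exponent.  The
focus is taken to track the surface (dynamic focusing), so z_f is constant
relative to the surface; defaults are z_f = 0 (surface-centered focus) and
z_R = 100 µm, the regime of a high-NA objective.

Estimation: each A-scan is re-indexed to depth-below-surface (linear
interpolation), averaged laterally over the B-scan — this averaging is the
speckle-reduction step (≈500 A-scans reduce the exponential-speckle CV of
the mean profile to ~4 %) — then fitted over a window of 200 µm of enamel
starting 10 µm below the surface (excluding the bright specular line).  The
default estimator divides by the confocal factor and fits ln I vs z by least
squares (µs = −slope/2): deterministic, scale-invariant, and exact on
noise-free model data.  A Levenberg–Marquardt fit of the full model (µs, I0
free; z_f, z_R fixed from the optics — jointly fitting them over a 200 µm
window is ill-conditioned) is available as a cross-check and agrees within
2 % on clean data.  R² is reported on the log scale in both cases.

## Calculus thickness (`octdent.calculus`)

The film's upper boundary is found exactly as the plain surface; the tooth
surface underneath is the next prominent local maximum below it (≥4 px
separation).  Candidate maxima are judged against the *enamel level just
below them* (height ≥ 2×, prominence ≥ 1×): the interface line brightens
with the film's backscatter while the substrate does not, so the detection
margin grows with film contrast — detection rate is genuinely non-decreasing
in film brightness — and speckle bumps riding on the film stay near their
own level.  Among qualifying candidates the brightest relative to its
substrate wins; a second threshold-crossing rule was rejected as
speckle-fragile.  Thickness = (bottom − top) optical distance / n_calc
(default 1.6, configurable and recorded in the output, since no measured
group index for calculus is established).  Two map-level cleanups exploit
that a real film is laterally contiguous with locally smooth thickness:
detections deviating >5 µm from their local 5×5 median thickness, or with
fewer than half their neighbors detected, are rejected; a mask-aware 3×3
median then smooths the map (the raw map is retained).  Fewer than 5 % valid
A-scans ⇒ "no calculus layer detected".

## Synthetic phantoms (`octdent.phantom`)

The generator emulates the statistical structure the estimators assume, with
exact ground truth:

- **Surface** = mean depth + waviness + roughness.  Waviness: sinusoid of
  configurable amplitude (10 µm) and period (500 µm) along the B-scan plus a
  weaker, slower cross-B-scan component, random phases.  Roughness:
  Gaussian random field band-limited to a 5 µm correlation length and
  renormalized to the target RMS *exactly*, making recovery tests sharp.
  The 5 µm default keeps the roughness spectrum well below the 70 µm
  form-cut (scale separability — "roughness" is only defined relative to
  the form filter) and above the 1.8 µm lateral resolution.
- **Depth signal** per the scattering model above, with a narrow specular
  Gaussian line (gain 4, σ = 1.2 px) at every refractive-index interface,
  scaled by the local incident level — under a bright film the
  calculus–enamel line rides on the film's illumination, as in real scans.
- **Speckle**: multiplicative unit-mean exponential intensity noise,
  independent per voxel (fully developed speckle).  **Floor**: exponential
  with configurable mean (10⁻⁴ of surface reflectivity).
- **Calculus**: a band of boosted backscatter (default 3×) between its own
  top surface and the tooth surface; configured thickness is geometric µm
  (the rendered optical band spans t·n_calc).
- **Interferograms**: Gaussian source envelope in λ times
  Σ cos(2kz + a₂(k−k₀)² + a₃(k−k₀)³), sampled uniformly in wavelength, with
  the known DC spectrum attached and an unambiguous-range check.
- **Randomness**: one integer seed feeding named seed-sequence sub-streams
  (surface, speckle per B-scan, floor, shot noise); identical config ⇒
  bit-identical volumes.

Presets encode the clinical group means (σ_r, µs) = (1.7, 2.85),
(3.7, 4.70), (6.6, 5.65) in µm and mm⁻¹; the calculus preset adds a
20–60 µm ramped film over a deeper (150 µm) mean surface so the film fits
in the volume.

**What the phantoms do not emulate** — and hence what passing tests do not
show about real teeth: no wave-optics propagation or depth-correlated
speckle, no multiple scattering (which biases µs estimates upward in highly
scattering tissue), no dentin layer or internal microstructure, no
birefringence, no refraction at the tilted surface, and the roughness is
stationary Gaussian whereas demineralized enamel is patchy.  Recovery
results certify the *estimators* under the stated noise model, not the
instrument or tissue.

## Problem sizes and accuracy budget

Default phantom volumes are 8 B-scans × 512 A-scans × 300 depth px
(1.0 µm lateral, 1.5 µm axial in air) — large enough that per-seed Rq means
are stable to a few percent and 512-A-scan lateral averaging tames speckle
for the µs fit; recovery suites use 20 seeds per preset (roughness) and
4-B-scan volumes over 5 seeds (scattering).  Known small biases, all
documented above and visible in the tests: lateral smoothing and despiking
attenuate recovered Rq by ~3–5 %, detection noise inflates it by a similar
amount at σ_r = 1.7 µm (net recovery within ±8 % on all presets);
µs recovery is unbiased to <1 % after averaging; calculus thickness is
recovered within ~0.5 µm with sub-pixel interface localization.

## Degenerate inputs and tie-breaks

Empty images, fully masked profiles, <10 usable A-scans or depth samples,
non-positive intensities in the log-linear fit, windows off the end of the
volume, and surfaces outside the rendered depth all raise `ValueError` with
the offending quantity named; truncations and >50 % detection failures warn
but proceed.  First-crossing ties take the shallowest index; the sub-pixel
step falls back to the crossing index when no decaying peak follows it
(step-like interfaces).  SE pixel counts round half-up to odd.
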