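# octdent — quantitative dental OCT analysis

Early dental caries roughens the enamel surface and raises its optical
scattering long before a cavity is visible, and dental calculus forms a thin
high-backscatter film on the tooth.  `octdent` implements the quantitative
analysis chain used with ultrahigh-resolution spectral-domain OCT (SD-OCT)
to measure these effects:

- **recon** — A-scan reconstruction from raw spectral interferograms:
  DC removal, k-linearization (uniform-wavelength → uniform-wavenumber
  resampling), windowing, polynomial dispersion compensation, FFT; plus
  resolution metrics (PSF FWHM, USAF-1951 bar widths, air ↔ tissue length
  conversion).
- **surface** — per-B-scan RMS surface roughness
  `Rq = sqrt((1/n) Σ z_i²)`, where the residuals `z_i` are the detected
  surface heights after the tooth's macroscopic form is removed with an
  alternating sequential grayscale morphological filter (flat structuring
  element, 70 µm by default).
- **scatter** — enamel scattering coefficient µs from the depth-resolved
  signal under a single-scattering model with dynamic-focusing compensation,
  `I(z) = I0 · exp(−2 µs z) / (1 + ((z − z_f)/z_R)²)`, fitted log-linearly
  after dividing out the confocal (Lorentzian) factor.  Exposed
  statsmodels-style: `ScatteringModel(z, I, …).fit()` returns a
  `ScatteringFit` with estimates, R² and a `summary()`.
- **calculus** — segmentation of the calculus film's upper surface and the
  underlying tooth surface per A-scan, yielding a thickness distribution
  map.
- **phantom** — a seeded synthetic tooth generator (wavy surface + controlled
  roughness, Beer–Lambert attenuation with confocal modulation, fully
  developed speckle, optional calculus film, raw interferogram synthesis)
  that provides exact ground truth for every estimator above.
- **report** — end-to-end orchestration with per-group mean/SD/95 %
  Student-t confidence intervals and reproducible CSV outputs.

Clinical-group presets encode the published group means: RMS roughness
1.7 / 3.7 / 6.6 µm and µs = 2.85 / 4.70 / 5.65 mm⁻¹ for sound enamel and
early-caries stages 1 and 2.

## Worked example

```python
from octdent import roughness_volume, scatter_volume
from octdent.phantom import preset, make_phantom

cfg = preset("caries_stage1", seed=42)      # sigma_r = 3.7 um, mu_s = 4.70 mm^-1
vol, truth = make_phantom(cfg)              # 8 x 512 x 300 voxel volume

results, rq = roughness_volume(vol, se_um=70.0)
print(f"Rq: mean {rq['mean']:.2f} um, SD {rq['sd']:.2f}, "
      f"95% CI ({rq['ci_low']:.2f}, {rq['ci_high']:.2f}), n = {rq['n']} B-scans")

fits, mu = scatter_volume(vol, cfg.system_spec(), window_um=200.0)
print(f"mu_s: mean {mu['mean']:.2f} mm^-1, SD {mu['sd']:.2f}, "
      f"95% CI ({mu['ci_low']:.2f}, {mu['ci_high']:.2f})")
print(fits[0].summary())
```

prints

```
Rq: mean 3.54 um, SD 0.49, 95% CI (3.14, 3.95), n = 8 B-scans
mu_s: mean 4.70 mm^-1, SD 0.02, 95% CI (4.68, 4.71)
Scattering-coefficient fit (single scattering + dynamic focusing)
----------------------------------------------------------------
  method        : log-linear
  mu_s          :     4.6807 mm^-1
  I0            :     0.9956
  R^2 (log fit) :     0.9954
  depth samples : 202
  window        : 188 um below surface
```

The roughness estimate (3.54 µm) recovers the phantom's configured 3.7 µm
RMS to within a few percent (small losses to the morphological form cut and
lateral smoothing; see `docs/methods.md`), and the scattering fit recovers
µs essentially exactly after speckle averaging over 512 A-scans per B-scan.

A command-line umbrella mirrors the library:

```sh
octdent phantom --preset caries_stage1 --seed 42 --out vol.tiff
octdent roughness --in vol.tiff --se-um 70 --out rq.csv
octdent scatter   --in vol.tiff --window-um 200 --out mus.csv
octdent calculus  --in vol.tiff --n-calc 1.6 --out thick.tiff
octdent run       --config run.json
```

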