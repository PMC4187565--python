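# fibroquant

Automated quantification of interstitial fibrosis on Sirius Red–stained
tissue sections imaged under polarization contrast.

## The problem

Interstitial fibrosis — pathological collagen accumulation between kidney
tubules — is the key structural readout of chronic kidney disease
progression, and is conventionally scored by eye on Masson trichrome
sections with a semiquantitative 0–5 ordinal scale. Manual scoring is
subjective and only moderately reproducible. Sirius Red binds collagen I/III
fibrils and enhances their birefringence, so under crossed polarizers
collagen appears bright on a near-black field; that stark contrast makes the
measurement automatable. `fibroquant` implements that automated measurement
for anyone quantifying fibrosis from single high-power fields or tiled
whole-section mosaics: image analysts, renal pathology labs, and preclinical
groups testing antifibrotic interventions.

## The method

Given a 12-bit grayscale polarization-contrast image and a kidney outline
(region of interest, ROI), the pipeline is:

1. **Background threshold.** Histogram the ROI pixel intensities (bin width
   1 over 0–4095). The background forms the dominant peak; measure its mode
   *m* and full width at half maximum *w* (half-max crossings by outward
   scan with linear interpolation). The threshold is

   *T* = *m* + 1.5 · *w*

   For a Gaussian background (*w* = 2.355 σ) this sits ≈ 3.5 σ above the
   mode, so false-positive area on signal-free background is ≈ 0.02 %.

2. **Perivascular mask.** Collagen sheathing blood vessels is strongly
   birefringent but is not interstitial fibrosis, and must be excluded.
   A three-step threshold–filter–threshold procedure finds it without
   locating vessels explicitly: (i) keep pixels above a high threshold
   (default *m* + 12 *w*); (ii) Gaussian-blur the resulting 0/1 mask
   (σ = 3 px), turning each pixel into the Gaussian-weighted fraction of its
   neighbourhood that is high-intensity; (iii) keep pixels where that
   fraction exceeds 0.35. Large bright clusters (vessel rings) survive with
   their margins expanded and lumens filled; small isolated bright speckle
   (an *n*-pixel cluster peaks at ≈ *n*/2πσ² after the blur) is suppressed.

3. **Percentage areas.** With *N*<sub>ROI</sub> pixels in the ROI and
   *N*<sub>above</sub> of them above *T*, of which *N*<sub>vessel</sub> fall
   inside the vessel mask:

   - total % = 100 · *N*<sub>above</sub> / *N*<sub>ROI</sub>
   - perivascular % = 100 · *N*<sub>vessel</sub> / *N*<sub>ROI</sub>
   - interstitial % = total − perivascular (exact partition)

The package also provides the ordinal 0–5 encoder for the classical bands
(<5, 5–10, 10–25, 25–50, 50–75, 75–100 %), per-field mean ± SEM summaries,
Pearson correlations for operator/section agreement studies, and a synthetic
field generator with exact per-pixel ground truth (noisy dark background,
thin intermediate-intensity fibrils, bright vessel rings, defocus and
polarizer-misalignment artefacts) used throughout the test suite.

## Worked example

Generate three synthetic fields and measure them:

```bash
$ fibroquant simulate --out demo --seed 7 --n-fields 3
wrote 3 synthetic field(s) to demo

$ fibroquant measure demo/field_000.tif --out demo/res.csv
field_000: total 2.789% | interstitial 2.789% | perivascular 0.000% (threshold 219.3)

$ fibroquant fields demo --out demo/fields.csv
3 fields: interstitial 2.781% +/- 0.013% (SEM)
```

`demo/manifest.csv` records the generator's ground truth for `field_000` as
2.771 % interstitial fraction; the pipeline measured 2.789 % with a
threshold of 219.3 derived from the field's own histogram (background mode
≈ 150, FWHM ≈ 46). Measuring the same manifest twice and correlating the
two result tables demonstrates exact repeatability:

```bash
$ fibroquant batch demo/manifest.csv --out demo/a.csv
$ fibroquant batch demo/manifest.csv --out demo/b.csv
$ fibroquant compare demo/a.csv demo/b.csv
r = 1.0000, p = 0, n = 3
```

`fibroquant report demo/field_000.tif --out demo/qc` writes the QC bundle:
overlays of counted and vessel-masked pixels, the annotated intensity
histogram, and a JSON summary.

From Python, the same measurement is:

```python
import fibroquant as fq

image = fq.read_image("demo/field_000.tif", bit_depth=12)
roi = fq.rasterize_roi(fq.read_roi_polygon("outline.json"), image.shape)  # optional
m = fq.run_pipeline(image, roi, fq.PipelineConfig())
print(m.interstitial_pct, m.perivascular_pct, m.threshold.value)
```

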