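# Methods

## Measurement model

The measurement assumes a polarization-contrast image in which (a) the
background dominates the pixel-count histogram as a single unimodal peak,
(b) collagen signal is strictly brighter than background, and (c)
perivascular collagen is distinguishable from interstitial fibrils not by
intensity alone but by *spatial coherence*: vessels present as large
contiguous clusters of high-intensity pixels around a dark lumen, while
interstitial fibrils are thin, dispersed, and mostly of intermediate
intensity with only rare small bright clusters.

### Background threshold

The ROI intensity histogram is built at bin width 1 over the full
representable range `[0, 2^bit_depth)`. The background peak mode `m` is the
centre of the globally maximal bin (ties resolve to the lowest intensity —
deterministic and biased toward the dark background, which is the peak we
want). The full width at half maximum `w` is found by scanning outward from
the mode and linearly interpolating between bin centres at the half-maximum
crossings; if one crossing is missing (a heavy one-sided tail reaching the
histogram edge) the other half-width is mirrored, and a single-bin spike
degenerates to `w = bin_width`. The threshold is `T = m + k*w` with
`k = 1.5` by default. Pixels *strictly above* `T` count as signal;
saturated pixels count as signal but are reported in `n_saturated` as a
quality flag.

Optional knobs, both off by default because the standard protocol does not
need them: a centred moving-average smoothing of the histogram before the
peak search (`smoothing_window`, for very sparse histograms) and a
restriction of the mode search to the lowest fraction of the intensity
range (`peak_search_fraction`, for pathological inputs whose brightest
material outweighs the background).

### Perivascular mask

Three steps: threshold at `high_threshold`, Gaussian-blur the resulting 0/1
mask, threshold the blurred field at `cluster_threshold`. Blurring the
*mask* rather than the raw intensities makes the second threshold a
scale-free quantity in [0, 1] — the Gaussian-weighted fraction of the
neighbourhood that is high-intensity — portable across exposure settings.

Defaults and why:

- `high_threshold = "mode+12*fwhm"`. The cutoff must sit above the
  intermediate-intensity band occupied by interstitial fibrils (up to
  ~`m + 10w` in the generator's model) and far below vessel-ring brightness
  (~85 % of saturation, i.e. ~`m + 70w` at typical background statistics).
  `m + 12w` clears the fibril band with margin; with the cutoff *inside*
  the fibril band, dense interstitial patches at high severity are
  misclassified as perivascular by several percentage points.
- `blur_sigma = 3 px` at 10× magnification. Sets the coherence scale:
  clusters much smaller than σ² pixels cannot reach high blurred values.
  σ is specified in pixels; rescale it in the config when working at a
  different magnification (no automatic rescaling from `pixel_size_um` —
  that would silently change results based on metadata).
- `cluster_threshold = 0.35`. An isolated n-pixel cluster peaks at
  ≈ `n/(2πσ²)` (≈ 0.018 n at σ = 3), so clusters under ~19 pixels are
  provably suppressed (`isolated_cluster_bound` computes the exact discrete
  bound); contiguous ring interiors sit near 1.0. The value also controls
  lumen filling: a lumen of radius r centred in a thick bright ring attains
  ≈ `exp(-r²/2σ²)` at its centre, so at σ = 3 lumens up to r ≈ 4.3 px fill
  completely and wider lumens fill only near the ring. Lumens of masked
  vessels that remain unmasked stay in the ROI denominator and, being dark,
  below threshold — they do not bias the percentages.

The blur uses reflective boundary padding so tissue at the image edge is
not artificially darkened, and the mask is computed on the whole image so
vessels truncated by the ROI outline are still masked.

### Percentages and statistics

`interstitial_pct` and `perivascular_pct` are computed from integer pixel
counts over the shared ROI denominator and `total_pct` is defined as their
sum, making the partition identity exact in floating point (the sum can
differ from `100*n_above/n_roi` by one ulp; the counts themselves are
always exact). Vessel-masked pixels below the background threshold remain
in the denominator. The ordinal encoder uses half-open bands
`[0,5) [5,10) [10,25) [25,50) [50,75) [75,100]`, with 100 in the top band.
SEM uses the n−1 sample standard deviation (0 for a single field). Pearson
p-values come from the exact t reference, `t = r*sqrt((n-2)/(1-r^2))` with
n−2 degrees of freedom; they are reported, never used for automated gating.

## ROI and image conventions

Pixels are 0-based `(row, col)`; polygon vertices are `(x=col, y=row)`.
A pixel belongs to the ROI when its centre lies inside the closed polygon
under the even-odd rule, implemented as a vectorized crossing-number test
with half-open edge handling so boundary pixels resolve deterministically.
Without a polygon the full image is the ROI. 12-bit data in 16-bit TIFF
containers is the expected input; the declared bit depth is validated on
load, and multi-channel or floating-point images are rejected rather than
silently converted. Mosaics are assembled from pre-registered, abutting
tiles with no interpolation or rescaling, conserving pixel count and
intensity sum exactly; no shading correction is applied.

## Synthetic fields

The generator emulates the three populations of a real field:

- **Background**: truncated Gaussian, default mode 150 / sd 20 (12-bit
  counts) — a dark, slightly noisy extinction background with a unimodal
  histogram so the threshold rule is well posed.
- **Fibrils**: random-orientation thick line segments (default 30 × 2 px),
  intensities drawn *per pixel*, uniform in `mode + [3, 10] × FWHM` — an
  intermediate band well above threshold but mostly below the vessel
  cutoff, matching the appearance of interstitial fibrils as predominantly
  intermediate with only scattered bright pixels. An optional disk
  (`fibril_region`) confines placement, emulating patchy cortical fibrosis.
- **Vessels**: bright annuli (default 85 % of saturation) around near-black
  lumens, drawn last so truth masks are disjoint (overlaps belong to
  vessels).

Truth masks are recorded at render time and match the drawn geometry
pixel-for-pixel; generation is deterministic given the scene seed.

Acquisition artefacts: `defocus` is a Gaussian low-pass of the intensities
re-quantized to integers; `misalign` adds a uniform background leak with
mean `full_transmission * sin²(angle)` carrying shot noise (variance
`shot_gain ×` mean, a linear camera-gain model with `shot_gain = 8` —
it is the leak's noise, not its mean, that erodes the signal-to-noise
ratio before saturation).

What the generator does **not** model: physical birefringence optics
(orientation-dependent fibril brightness, Mueller-matrix effects), stain
chemistry and section-thickness variation, tubular autofluorescence,
vignetting/shading across mosaic tiles, and vessels of non-annular
geometry. Passing tests therefore demonstrate the *algorithmic* contracts
(threshold rule, mask semantics, partition arithmetic, recovery on scenes
matching the model), not performance on tissue.

## Validation harnesses

`fibroquant.validation` holds the experiments the test suite and
`scripts/acceptance.py` run; problem sizes were chosen so the whole battery
completes in seconds:

- **Threshold recovery**: 10⁶ samples of a Gaussian background (μ = 100,
  σ = 20) reshaped into an image; recovered mode and FWHM are compared to μ
  and 2.355 σ.
- **Recovery study**: 50 fields of 256 × 256 px with fibril counts ramping
  so realized truth spans ~1–20 % — the per-field severity range over which
  the method is expected to operate; full pipeline, default config.
- **Focus series**: measured area at defocus σ ∈ {0, 1, 2, 4} px with the
  threshold *fixed at its in-focus value*. Re-deriving the threshold from
  an already-blurred exposure would collapse the recorded noise's FWHM and
  the threshold with it — an artefact of blurring sampled noise that real
  refocused exposures do not exhibit — so the fixed threshold is the
  faithful analogue of constant acquisition settings. The minimal-fibrosis
  field uses fine dim fibrils (1 px wide, intensity `mode + [1.8, 3] ×
  FWHM`): blur dilutes their thin profiles below threshold, and measured
  area falls. The substantial-fibrosis field uses thick bright bundles
  (4 px) clustered in a patch: blur spreads their margins while interiors
  stay above threshold, and measured area grows. This severity-dependent
  morphology — fine early fibrils versus coarse mature bundles — is the
  package's model of why the defocus direction flips with severity.
- **Misalignment series**: SNR (mean signal intensity over background
  standard deviation) at 0°, 2°, 5°, 10° of polarizer misalignment.

## Numerical choices and degenerate inputs

- Histogram ties at the maximum → lowest-intensity bin; flat plateau at the
  mode → `fwhm = bin_width` fallback.
- All-zero histograms, empty ROIs, degenerate polygons (< 3 vertices or
  zero area), zero-variance correlation inputs and mismatched shapes raise
  `ValueError` rather than returning sentinel values.
- The config `high_threshold` accepts an absolute intensity or a
  `"mode+N*fwhm"` expression resolved per image; the pipeline refuses to
  run if the resolved value does not exceed the background threshold.
- Every result row carries a 12-hex-digit SHA-256 fingerprint of the full
  config, so equal fingerprints plus equal inputs imply equal outputs.

## Known limitations

- The threshold rule presumes the background is the histogram's global
  maximum; fields dominated by bright material need `peak_search_fraction`.
- Vessel-mask parameters are calibrated on the generator's geometry; tissue
  with unusually large lumens (> ~4 px at σ = 3) will retain unmasked dark
  lumen area (harmless for the percentages) and very dense mature fibrosis
  with genuinely bright bundles may partially enter the vessel mask if the
  high threshold is set inside the bright band.
- No stitching registration or shading correction: mosaics are assumed
  pre-registered and flat-field corrected upstream.
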