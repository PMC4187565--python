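"""Fibrosis percentage areas, ordinal scores and reproducibility statistics.

Fibrosis is the percentage of unmasked above-threshold pixels relative to
total pixels within the region of interest:

    F_total        = 100 * n_above / n_roi
    F_perivascular = 100 * (n_above inside vessel mask) / n_roi
    F_interstitial = F_total - F_perivascular

All three share the ROI denominator, so interstitial + perivascular =
total exactly on every measurement.  Vessel-masked pixels *below* the
background threshold stay in the denominator.

The module also carries the validation statistics used to characterize the
method: per-field mean +/- SEM summaries and Pearson correlations (e.g.
same-operator repeat runs, two operators, left vs right kidney).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .io import GrayscaleImage, RegionOfInterest
from .thresholding import (
    BackgroundThreshold,
    apply_threshold,
    background_threshold,
    compute_histogram,
    find_background_peak,
)
from .vessels import VesselMask, VesselMaskParams, perivascular_mask

#: Ordinal severity bands, half-open [lo, hi); 100% belongs to the top band.
ORDINAL_BANDS = [(0, 5), (5, 10), (10, 25), (25, 50), (50, 75), (75, 100)]


@dataclass
class FibrosisMeasurement:
    """Percentage areas plus the pixel counts and threshold behind them."""

    total_pct: float
    interstitial_pct: float
    perivascular_pct: float
    n_roi: int
    n_above: int
    n_above_vessel: int
    n_above_interstitial: int
    threshold: BackgroundThreshold
    n_saturated: int = 0
    image_id: str = ""
    config_fingerprint: str = ""

    def __post_init__(self) -> None:
        for name in ("total_pct", "interstitial_pct", "perivascular_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.n_above_interstitial + self.n_above_vessel != self.n_above:
            raise ValueError("pixel counts do not partition")

    def to_row(self) -> dict:
        """Flatten into one results-table row."""
        return {
            "image_id": self.image_id,
            "threshold": self.threshold.value,
            "mode": self.threshold.provenance.mode,
            "fwhm": self.threshold.provenance.fwhm,
            "multiplier": self.threshold.multiplier,
            "total_pct": self.total_pct,
            "interstitial_pct": self.interstitial_pct,
            "perivascular_pct": self.perivascular_pct,
            "n_roi": self.n_roi,
            "n_above": self.n_above,
            "n_above_vessel": self.n_above_vessel,
            "n_above_interstitial": self.n_above_interstitial,
            "n_saturated": self.n_saturated,
            "config_fingerprint": self.config_fingerprint,
        }


@dataclass
class OrdinalScore:
    """Semiquantitative 0-5 severity category and the band it encodes."""

    category: int
    band: tuple[float, float]


@dataclass
class FieldSummary:
    """Mean +/- SEM over nonoverlapping fields of one section."""

    n_fields: int
    mean: float
    sem: float


@dataclass
class CorrelationResult:
    """Pearson product-moment correlation with its two-sided p-value."""

    r: float
    p_value: float
    n: int


def measure_fibrosis(
    image: GrayscaleImage,
    roi: RegionOfInterest | None,
    threshold: BackgroundThreshold,
    vessel_mask: VesselMask | None = None,
    image_id: str = "",
    config_fingerprint: str = "",
) -> FibrosisMeasurement:
    """Count above-threshold ROI pixels and partition them by the vessel mask.

    With ``vessel_mask=None`` every above-threshold pixel is interstitial.
    Saturated pixels (intensity = 2**bit_depth - 1) count as above threshold
    but are reported in ``n_saturated`` as a quality flag.
    """
    if roi is None:
        roi_mask = np.ones(image.shape, dtype=bool)
    else:
        if roi.mask.shape != image.shape:
            raise ValueError("ROI dimensions do not match image")
        roi_mask = roi.mask
    above = apply_threshold(image, threshold) & roi_mask
    n_roi = int(roi_mask.sum())
    n_above = int(above.sum())
    if vessel_mask is not None:
        if vessel_mask.mask.shape != image.shape:
            raise ValueError("vessel mask dimensions do not match image")
        n_vessel = int((above & vessel_mask.mask).sum())
    else:
        n_vessel = 0
    n_interstitial = n_above - n_vessel
    interstitial_pct = 100.0 * n_interstitial / n_roi
    perivascular_pct = 100.0 * n_vessel / n_roi
    n_saturated = int((image.pixels[roi_mask] == image.max_intensity).sum())
    return FibrosisMeasurement(
        # summing the two parts keeps the partition identity exact in floats
        total_pct=interstitial_pct + perivascular_pct,
        interstitial_pct=interstitial_pct,
        perivascular_pct=perivascular_pct,
        n_roi=n_roi,
        n_above=n_above,
        n_above_vessel=n_vessel,
        n_above_interstitial=n_interstitial,
        threshold=threshold,
        n_saturated=n_saturated,
        image_id=image_id,
        config_fingerprint=config_fingerprint,
    )


def ordinal_score(pct: float) -> OrdinalScore:
    """Map a percentage area onto the 0-5 semiquantitative scale.

    Bands are <5, 5-10, 10-25, 25-50, 50-75 and 75-100 percent, half-open
    at the top except that 100 belongs to category 5.
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage {pct} outside [0, 100]")
    for category, (lo, hi) in enumerate(ORDINAL_BANDS):
        if lo <= pct < hi or (category == 5 and pct == 100):
            return OrdinalScore(category=category, band=(lo, hi))
    raise AssertionError("unreachable: bands partition [0, 100]")


def field_summary(values) -> FieldSummary:
    """Mean and standard error over per-field percentages or scores.

    SEM uses the n-1 sample standard deviation and is 0 for a single field.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no field values")
    n = values.size
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return FieldSummary(n_fields=int(n), mean=float(values.mean()), sem=sem)


def pearson_r(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p-value from the exact t reference.

    Requires n >= 3 paired values and nonzero variance in both lists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


def run_pipeline(
    image: GrayscaleImage,
    roi: RegionOfInterest | None = None,
    config: PipelineConfig | None = None,
    image_id: str = "",
) -> FibrosisMeasurement:
    """Full measurement: histogram -> peak -> threshold -> vessel mask -> areas.

    Deterministic given image + config: no randomness anywhere in the
    measurement path.  The vessel mask is computed on the whole image (so
    vessels truncated by the outline are still masked) and intersected with
    the ROI implicitly by the counting step.
    """
    config = config or PipelineConfig()
    hist = compute_histogram(image, roi, bin_width=config.bin_width)
    peak = find_background_peak(
        hist,
        smoothing_window=config.smoothing_window,
        peak_search_fraction=config.peak_search_fraction,
    )
    thr = background_threshold(peak, multiplier=config.multiplier)
    vmask = None
    if config.mask_vessels:
        high = config.resolve_high_threshold(peak.mode, peak.fwhm)
        if high <= thr.value:
            raise ValueError(
                f"high_threshold {high} must exceed background threshold {thr.value}"
            )
        params = VesselMaskParams(
            high_threshold=high,
            blur_sigma=config.blur_sigma_px,
            cluster_threshold=config.cluster_threshold,
        )
        vmask = perivascular_mask(image, params)
    return measure_fibrosis(
        image,
        roi,
        thr,
        vmask,
        image_id=image_id,
        config_fingerprint=config.fingerprint(),
    )
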