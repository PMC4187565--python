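"""QC report bundles: overlay images and the annotated intensity histogram.

Automated thresholds still deserve operator review; the bundle renders the
panels a microscopist would check by eye — which pixels were counted, where
the vessel mask fell, and where the threshold sits on the histogram.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import imageio.v3 as iio
import numpy as np

from .io import GrayscaleImage, RegionOfInterest
from .quantify import FibrosisMeasurement
from .thresholding import compute_histogram
from .vessels import VesselMask


def _to_rgb(image: GrayscaleImage) -> np.ndarray:
    scaled = (image.pixels.astype(float) / image.max_intensity * 255).astype(np.uint8)
    return np.stack([scaled] * 3, axis=-1)


def _overlay(base: np.ndarray, mask: np.ndarray, color: tuple[int, int, int]) -> np.ndarray:
    out = base.copy()
    out[np.asarray(mask, bool)] = color
    return out


def qc_report(
    measurement: FibrosisMeasurement,
    image: GrayscaleImage,
    roi: RegionOfInterest | None = None,
    vessel_mask: VesselMask | None = None,
    out_dir: str | Path = ".",
) -> dict[str, Path]:
    """Write the QC bundle; returns a name -> path map.

    Contents: three overlay PNGs (above-threshold pixels in red, vessel
    mask in blue, ROI in green), the intensity histogram annotated with
    mode, FWHM and the applied threshold, and a JSON measurement summary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = _to_rgb(image)
    thr = measurement.threshold
    above = image.pixels > thr.value
    roi_mask = roi.mask if roi is not None else np.ones(image.shape, dtype=bool)
    vmask = vessel_mask.mask if vessel_mask is not None else np.zeros(image.shape, bool)

    paths = {
        "threshold_overlay": out_dir / "threshold_overlay.png",
        "vessel_overlay": out_dir / "vessel_overlay.png",
        "roi_overlay": out_dir / "roi_overlay.png",
        "histogram": out_dir / "histogram.png",
        "summary": out_dir / "summary.json",
    }
    iio.imwrite(paths["threshold_overlay"], _overlay(base, above & roi_mask, (255, 0, 0)))
    iio.imwrite(paths["vessel_overlay"], _overlay(base, vmask, (0, 80, 255)))
    iio.imwrite(paths["roi_overlay"], _overlay(base, ~roi_mask, (0, 120, 0)))

    hist = compute_histogram(image, roi)
    peak = thr.provenance
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(hist.bin_centers, hist.counts, lw=0.8, color="k")
    ax.axvline(peak.mode, color="tab:blue", label=f"mode = {peak.mode:.1f}")
    ax.axvspan(
        peak.mode - peak.fwhm / 2,
        peak.mode + peak.fwhm / 2,
        color="tab:blue",
        alpha=0.15,
        label=f"FWHM = {peak.fwhm:.1f}",
    )
    ax.axvline(thr.value, color="tab:red", label=f"threshold = {thr.value:.1f}")
    upper = thr.value + 5 * peak.fwhm
    ax.set_xlim(0, max(upper, peak.mode + 3 * peak.fwhm))
    ax.set_xlabel("pixel intensity")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(paths["histogram"], dpi=120)
    plt.close(fig)

    summary = measurement.to_row()
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return paths
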