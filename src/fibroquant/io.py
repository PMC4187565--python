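"""Image, region-of-interest and result-table input/output.

Polarization-contrast acquisitions are single-channel intensity images,
typically 12-bit data (0–4095) stored in 16-bit TIFF containers.  Whole
kidney sections are acquired as row-major grids of abutting 10x tiles and
assembled into one mosaic before measurement.  The kidney outline arrives
as a closed polygon (manually drawn in the acquisition software) and is
rasterized to a binary inclusion mask that defines the denominator of every
percentage-area value downstream.

Conventions
-----------
Pixel indices are 0-based ``(row, col)``.  Polygon vertices are ``(x, y)``
with ``x`` the column and ``y`` the row.  A pixel belongs to the ROI when
its *centre* ``(col, row)`` lies inside the closed polygon under the
even-odd rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class ImageFormatError(ValueError):
    """Raised for images that violate the single-channel integer contract."""


@dataclass
class GrayscaleImage:
    """A single-channel intensity image with bit-depth metadata.

    Parameters
    ----------
    pixels
        2-D integer array of intensities.
    bit_depth
        Declared bit depth; all intensities must lie in
        ``[0, 2**bit_depth - 1]``.  Defaults to 12 (0–4095), the usual
        scientific-camera output even when stored as 16-bit TIFF.
    pixel_size_um
        Optional physical pixel size in micrometres.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImageFormatError(
                f"expected a 2-D single-channel image, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ImageFormatError("image must contain at least one pixel")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ImageFormatError(
                f"expected integer intensities, got dtype {self.pixels.dtype}; "
                "convert floating-point data explicitly before constructing"
            )
        lo = int(self.pixels.min())
        hi = int(self.pixels.max())
        cap = self.max_intensity
        if lo < 0 or hi > cap:
            raise ImageFormatError(
                f"intensities [{lo}, {hi}] exceed declared {self.bit_depth}-bit "
                f"range [0, {cap}]"
            )

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RegionOfInterest:
    """Binary inclusion mask, optionally carrying its source polygon."""

    mask: np.ndarray
    source_polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI includes no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TileLayout:
    """Row-major grid of pre-registered, abutting tiles."""

    rows: int
    cols: int
    tiles: Sequence[GrayscaleImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if len(self.tiles) != self.rows * self.cols:
            raise ValueError(
                f"layout {self.rows}x{self.cols} needs {self.rows * self.cols} "
                f"tiles, got {len(self.tiles)}"
            )
        first = self.tiles[0]
        for t in self.tiles[1:]:
            if t.shape != first.shape:
                raise ValueError("all tiles must share dimensions")
            if t.bit_depth != first.bit_depth:
                raise ValueError("all tiles must share bit depth")


def read_image(
    path: str | Path,
    bit_depth: int | None = 12,
    pixel_size_um: float | None = None,
) -> GrayscaleImage:
    """Read a single-channel TIFF (or PNG) into a :class:`GrayscaleImage`.

    ``bit_depth`` is the *declared* depth of the data, not the container:
    12-bit cameras write 16-bit files.  Pass ``None`` to infer the depth
    from the container dtype (uint8 -> 8, uint16 -> 16).  Multi-channel or
    floating-point files are rejected; intensities exceeding the declared
    depth raise :class:`ImageFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        raise ImageFormatError(
            f"{path.name}: multi-channel image (shape {pixels.shape}); the "
            "pipeline is defined on the grayscale polarization signal"
        )
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ImageFormatError(
            f"{path.name}: floating-point pixels ({pixels.dtype}) need an "
            "explicit conversion before analysis"
        )
    if bit_depth is None:
        bit_depth = pixels.dtype.itemsize * 8
    return GrayscaleImage(pixels, bit_depth=bit_depth, pixel_size_um=pixel_size_um)


def write_image(image: GrayscaleImage, path: str | Path) -> None:
    """Write to TIFF (16-bit container for depths > 8) or PNG."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
    pixels = image.pixels.astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Export a binary mask as an 8-bit 0/255 PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (crossing-number) point-in-polygon test.

    Edges are treated half-open in y so each horizontal ray crossing is
    counted exactly once; results are deterministic for points on edges.
    """
    inside = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= crosses & (px < xint)
    return inside


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def rasterize_roi(
    polygon: Sequence[Sequence[float]] | np.ndarray | None,
    shape: tuple[int, int],
) -> RegionOfInterest:
    """Rasterize a closed outline polygon to a binary inclusion mask.

    A pixel ``(row, col)`` is included when its centre ``(x=col, y=row)``
    falls inside the polygon under the even-odd rule.  With ``polygon=None``
    the whole image is the ROI (e.g. single high-power fields).
    """
    h, w = shape
    if polygon is None:
        return RegionOfInterest(np.ones((h, w), dtype=bool))
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    if _polygon_area(poly) == 0.0:
        raise ValueError("degenerate polygon with zero area")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = _points_in_polygon(xx.astype(float), yy.astype(float), poly)
    return RegionOfInterest(mask, source_polygon=poly)


def read_roi_polygon(path: str | Path) -> np.ndarray:
    """Read an outline polygon from JSON or ImageJ-style two-column text.

    JSON: either a bare list ``[[x, y], ...]`` or ``{"polygon": [[x, y], ...]}``.
    Text: one ``x y`` pair per line (whitespace separated), as produced by
    ImageJ's "save XY coordinates".
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        obj = json.loads(text)
        if isinstance(obj, dict):
            obj = obj["polygon"]
        poly = np.asarray(obj, dtype=float)
    else:
        rows = [line.split() for line in text.splitlines() if line.strip()]
        poly = np.asarray(rows, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise ValueError(f"{path.name}: expected two columns of x y vertices")
    return poly


def assemble_mosaic(layout: TileLayout) -> GrayscaleImage:
    """Assemble a row-major tile grid into one whole-section image.

    Tiles are placed abutting, without overlap, interpolation or intensity
    rescaling, so pixel count and intensity sum are conserved exactly.
    """
    first = layout.tiles[0]
    grid = [
        [layout.tiles[r * layout.cols + c].pixels for c in range(layout.cols)]
        for r in range(layout.rows)
    ]
    return GrayscaleImage(
        np.block(grid), bit_depth=first.bit_depth, pixel_size_um=first.pixel_size_um
    )


#: Column order of the results table written by :func:`write_results`.
RESULT_COLUMNS = [
    "image_id",
    "threshold",
    "mode",
    "fwhm",
    "multiplier",
    "total_pct",
    "interstitial_pct",
    "perivascular_pct",
    "n_roi",
    "n_above",
    "n_above_vessel",
    "n_above_interstitial",
    "n_saturated",
    "config_fingerprint",
]


def write_results(measurements: Sequence, path: str | Path) -> pd.DataFrame:
    """Write one CSV row per measurement; returns the DataFrame written.

    Floats are written at full precision so a read-back reproduces every
    numeric field exactly.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements to write")
    rows = [m.to_row() for m in measurements]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(path)
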