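"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check:
``brute_force_point_in_polygon`` is a scalar per-pixel crossing test,
``dense_blur_oracle`` builds an explicit 2-D Gaussian kernel and convolves
it densely with reflective padding.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import convolve2d

import fibroquant as fq


def brute_force_point_in_polygon(x: float, y: float, poly) -> bool:
    """Scalar even-odd crossing-number test for one point."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = (x2 - x1) * (y - y1) / (y2 - y1) + x1
            if x < xint:
                inside = not inside
    return inside


def dense_blur_oracle(mask: np.ndarray, sigma: float) -> np.ndarray:
    """Dense 2-D convolution with an explicit truncated normalized kernel."""
    r = int(4 * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    # np.pad "symmetric" == ndimage's "reflect" (edge pixel repeated)
    padded = np.pad(np.asarray(mask, dtype=float), r, mode="symmetric")
    return convolve2d(padded, kernel, mode="valid")


def constant_image(value: int, shape=(16, 16), bit_depth: int = 12) -> fq.GrayscaleImage:
    return fq.GrayscaleImage(np.full(shape, value, dtype=np.int64), bit_depth=bit_depth)


@pytest.fixture
def vessel_scene():
    """One bright ring (inner r=4, outer r=12) on a clean noisy background."""
    spec = fq.SceneSpec(
        shape=(128, 128),
        fibril_count=0,
        vessels=[
            fq.VesselSpec(center=(64, 64), inner_radius=4, outer_radius=12, ring_intensity=3800)
        ],
        seed=11,
    )
    return fq.generate_field(spec)


@pytest.fixture
def default_params():
    return fq.VesselMaskParams(high_threshold=2000, blur_sigma=3, cluster_threshold=0.35)
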