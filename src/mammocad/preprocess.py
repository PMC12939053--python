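"""ROI extraction ("cutting"), median denoising, and contrast enhancement.

The preprocessing chain mirrors standard mammography CAD practice: the
region of interest is cut from the full mammogram using the annotated lesion
center and radius, impulse noise is suppressed with a 3x3 median filter
(which preserves edges and microcalcification-scale detail), and global
histogram equalization redistributes intensities to raise lesion/background
contrast before texture analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import GrayImage


@dataclass(frozen=True)
class ROISpec:
    """Square crop of side ``2 * radius`` centered on the annotated lesion."""

    center_x: int
    center_y: int
    radius: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def extract_roi(image: GrayImage, roi: ROISpec) -> GrayImage:
    """Cut the axis-aligned square of side 2*radius centered on the lesion.

    The window is clipped to the image bounds, so ROIs near an edge come back
    smaller.  Pixel values are untouched.
    """
    cx, cy, r = roi.center_x, roi.center_y, roi.radius
    if not (0 <= cx < image.width and 0 <= cy < image.height):
        raise ValueError(
            f"ROI center ({cx}, {cy}) outside image {image.width}x{image.height}"
        )
    row_lo, row_hi = max(cy - r, 0), min(cy + r, image.height)
    col_lo, col_hi = max(cx - r, 0), min(cx + r, image.width)
    return GrayImage(image.pixels[row_lo:row_hi, col_lo:col_hi].copy(), image.bit_depth)


def median_filter_3x3(image: GrayImage) -> GrayImage:
    """3x3 median filter with edge replication at the borders."""
    filtered = ndimage.median_filter(image.pixels, size=3, mode="nearest")
    return GrayImage(filtered, image.bit_depth)


def equalize_histogram(image: GrayImage) -> GrayImage:
    """Classic global histogram equalization on the full dynamic range.

    out(v) = round((L-1) * (cdf(v) - cdf_min) / (1 - cdf_min)) with
    L = 2**bit_depth and cdf_min the cdf at the lowest occupied bin.  The
    mapping is monotone non-decreasing; a constant image (single occupied
    bin) maps to 0.
    """
    levels = 1 << image.bit_depth
    hist = np.bincount(image.pixels.ravel(), minlength=levels)
    cdf = np.cumsum(hist) / image.pixels.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf_min >= 1.0:  # single occupied bin
        lut = np.zeros(levels, dtype=np.int64)
    else:
        lut = np.rint((levels - 1) * (cdf - cdf_min) / (1.0 - cdf_min)).astype(np.int64)
        lut = np.clip(lut, 0, levels - 1)
    return GrayImage(lut[image.pixels], image.bit_depth)


def stretch_contrast(image: GrayImage) -> GrayImage:
    """Linear min-max contrast stretching (alternative to equalization)."""
    pix = image.pixels.astype(np.float64)
    lo, hi = pix.min(), pix.max()
    if hi == lo:
        return GrayImage(np.zeros_like(image.pixels), image.bit_depth)
    out = np.rint((pix - lo) / (hi - lo) * image.max_value)
    return GrayImage(out, image.bit_depth)


def preprocess_pipeline(
    image: GrayImage, roi: ROISpec, contrast: str = "equalize"
) -> GrayImage:
    """ROI cut -> 3x3 median filter -> contrast enhancement, in that order.

    ``contrast`` is ``"equalize"`` (default), ``"stretch"``, or ``"none"``.
    """
    out = median_filter_3x3(extract_roi(image, roi))
    if contrast == "equalize":
        out = equalize_histogram(out)
    elif contrast == "stretch":
        out = stretch_contrast(out)
    elif contrast != "none":
        raise ValueError(f"unknown contrast mode {contrast!r}")
    return out
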