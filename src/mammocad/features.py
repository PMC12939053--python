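"""The 104-dimensional feature vector for a preprocessed mass ROI.

Three blocks, concatenated in a fixed canonical order:

* 88 texture features: 22 gray-level co-occurrence matrix (GLCM) statistics
  — the classic Haralick (1973) set extended by Soh & Tsatsoulis (1999) and
  Clausi (2002) — computed at the four offsets 0°, 45°, 90°, 135°
  (stat-major ordering: all four angles of a statistic are adjacent);
* 6 first-order histogram features (mean, variance, skewness, kurtosis,
  energy, entropy of the normalized intensity histogram);
* 10 region/shape descriptors of the segmented mass (solidity, area, axis
  lengths, convex area, eccentricity, orientation, perimeter, extent,
  equivalent diameter).

Benign masses tend to be compact with smooth margins (high solidity, low
perimeter-to-area ratio) while malignant masses are spiculated and
texturally heterogeneous (low solidity, high GLCM contrast/entropy); the
feature set is designed around exactly that contrast.

Conventions (documented because several have competing definitions):
co-occurrence entropies use the natural logarithm with 0·log 0 = 0; GLCM
statistics index gray levels 1..L (MATLAB-style), which matters for the
index-dependent statistics (autocorrelation, cluster shade/prominence, sum
statistics); sum variance is taken about the sum average; orientation is the
angle from the horizontal (column) axis in degrees, range (−90°, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .io import FeatureTable, GrayImage

GLCM_ANGLES = (0, 45, 90, 135)

#: offsets in (row, col) for each angle at distance d; rows grow downward so
#: 45° (up-right on screen) is (-d, +d)
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_STAT_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "correlation_matlab",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "sum_of_squares_variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "info_correlation_1",
    "info_correlation_2",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

HISTOGRAM_FEATURE_NAMES = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_entropy",
)

SHAPE_FEATURE_NAMES = (
    "shape_solidity",
    "shape_area",
    "shape_major_axis_length",
    "shape_minor_axis_length",
    "shape_convex_area",
    "shape_eccentricity",
    "shape_orientation",
    "shape_perimeter",
    "shape_extent",
    "shape_equiv_diameter",
)

#: canonical 104-feature order: GLCM block (stat-major), histogram, shape
FEATURE_NAMES: list[str] = (
    [f"{stat}_a{angle}" for stat in GLCM_STAT_NAMES for angle in GLCM_ANGLES]
    + list(HISTOGRAM_FEATURE_NAMES)
    + list(SHAPE_FEATURE_NAMES)
)
assert len(FEATURE_NAMES) == 104


class SegmentationError(ValueError):
    """Raised when no mass region can be segmented from an ROI."""


@dataclass(frozen=True)
class GLCM:
    """A normalized co-occurrence matrix p(i, j) at one offset."""

    matrix: np.ndarray
    levels: int
    angle: int
    distance: int


def quantize(image: GrayImage, levels: int) -> np.ndarray:
    """Uniformly bin the full dynamic range [0, 2**bit_depth) into ``levels``."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    full_range = 1 << image.bit_depth
    binned = (image.pixels.astype(np.int64) * levels) // full_range
    return np.minimum(binned, levels - 1)


def compute_glcm(
    quantized: np.ndarray,
    angle: int,
    distance: int = 1,
    levels: int | None = None,
    symmetric: bool = True,
) -> GLCM:
    """Count co-occurrences of gray levels at the given angular offset.

    Angle-to-offset convention in (row, col): 0° -> (0, +d), 45° -> (-d, +d),
    90° -> (-d, 0), 135° -> (-d, -d).  With ``symmetric`` accumulation the
    transpose is added before normalizing to a joint probability matrix.
    """
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {GLCM_ANGLES}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    quantized = np.asarray(quantized)
    if levels is None:
        levels = int(quantized.max()) + 1
    dr, dc = (distance * o for o in _ANGLE_OFFSETS[angle])
    h, w = quantized.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("image too small for the requested offset")
    src = quantized[r0:r1, c0:c1].ravel()
    dst = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (src, dst), 1.0)
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts / counts.sum(), levels, angle, distance)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def glcm_feature_set(glcm: GLCM) -> dict[str, float]:
    """The 22 co-occurrence statistics, keyed by canonical name.

    Degenerate guards: statistics normalized by a zero marginal deviation
    (both correlation variants) or a zero marginal entropy (information
    measure of correlation 1) are defined as 0.
    """
    p = np.asarray(glcm.matrix, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("GLCM must be a normalized probability matrix")
    n = p.shape[0]
    i = np.arange(1, n + 1)[:, None].astype(np.float64)  # 1-based row level
    j = np.arange(1, n + 1)[None, :].astype(np.float64)

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i[:, 0] * px).sum())
    mu_y = float((j[0, :] * py).sum())
    sd_x = float(np.sqrt(((i[:, 0] - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((j[0, :] - mu_y) ** 2 * py).sum()))

    diff = i - j
    abs_diff = np.abs(diff)
    summ = i + j

    # p_{x+y}(k), k = 2..2n and p_{x-y}(k), k = 0..n-1
    p_sum = np.zeros(2 * n + 1)
    np.add.at(p_sum, summ.astype(int), p)
    p_diff = np.zeros(n)
    np.add.at(p_diff, abs_diff.astype(int), p)
    k_sum = np.arange(2 * n + 1, dtype=np.float64)
    k_diff = np.arange(n, dtype=np.float64)

    autocorrelation = float((i * j * p).sum())
    contrast = float((diff**2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float((((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_y))
        correlation_matlab = (autocorrelation - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = correlation_matlab = 0.0
    dev = summ - mu_x - mu_y
    cluster_prominence = float((dev**4 * p).sum())
    cluster_shade = float((dev**3 * p).sum())
    dissimilarity = float((abs_diff * p).sum())
    energy = float((p**2).sum())
    entropy = _entropy(p.ravel())
    homogeneity = float((p / (1.0 + diff**2)).sum())
    inverse_difference = float((p / (1.0 + abs_diff)).sum())
    maximum_probability = float(p.max())
    sum_of_squares_variance = float(((i - mu_x) ** 2 * p).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    pxy = px[:, None] * py[None, :]
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[mask] * np.log(pxy[mask])).sum())
    mask2 = pxy > 0
    hxy2 = float(-(pxy[mask2] * np.log(pxy[mask2])).sum())
    denom = max(hx, hy)
    info_correlation_1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    info_correlation_2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    inverse_difference_normalized = float((p / (1.0 + abs_diff / n)).sum())
    inverse_difference_moment_normalized = float((p / (1.0 + diff**2 / n**2)).sum())

    values = (
        autocorrelation,
        contrast,
        correlation,
        correlation_matlab,
        cluster_prominence,
        cluster_shade,
        dissimilarity,
        energy,
        entropy,
        homogeneity,
        maximum_probability,
        sum_of_squares_variance,
        sum_average,
        sum_variance,
        sum_entropy,
        difference_variance,
        difference_entropy,
        info_correlation_1,
        info_correlation_2,
        inverse_difference,
        inverse_difference_normalized,
        inverse_difference_moment_normalized,
    )
    return dict(zip(GLCM_STAT_NAMES, values))


def glcm_block(
    image: GrayImage, distance: int = 1, levels: int = 8, symmetric: bool = True
) -> dict[str, float]:
    """All 22 statistics at the four angles (88 values, stat-major order)."""
    quantized = quantize(image, levels)
    per_angle = {
        angle: glcm_feature_set(
            compute_glcm(quantized, angle, distance, levels, symmetric)
        )
        for angle in GLCM_ANGLES
    }
    return {
        f"{stat}_a{angle}": per_angle[angle][stat]
        for stat in GLCM_STAT_NAMES
        for angle in GLCM_ANGLES
    }


def histogram_feature_set(image: GrayImage) -> dict[str, float]:
    """First-order statistics of the normalized intensity histogram.

    Skewness and kurtosis are defined as 0 when the intensity variance is 0.
    """
    levels = 1 << image.bit_depth
    h = np.bincount(image.pixels.ravel(), minlength=levels) / image.pixels.size
    v = np.arange(levels, dtype=np.float64)
    mean = float((v * h).sum())
    variance = float(((v - mean) ** 2 * h).sum())
    sd = np.sqrt(variance)
    if sd > 0:
        skewness = float((((v - mean) / sd) ** 3 * h).sum())
        kurtosis = float((((v - mean) / sd) ** 4 * h).sum())
    else:
        skewness = kurtosis = 0.0
    energy = float((h**2).sum())
    entropy = _entropy(h)
    return dict(
        zip(
            HISTOGRAM_FEATURE_NAMES,
            (mean, variance, skewness, kurtosis, energy, entropy),
        )
    )


def segment_mass_mask(roi_image: GrayImage) -> np.ndarray:
    """Segment the mass: Otsu threshold, largest 8-connected component,
    hole filling.  Returns a boolean mask the same shape as the ROI."""
    pix = roi_image.pixels
    if pix.min() == pix.max():
        raise SegmentationError("constant ROI: no threshold separates a mass")
    mask = pix > threshold_otsu(pix)
    labels, n_components = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_components == 0:
        raise SegmentationError("no foreground component above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_components + 1))
    largest = int(np.argmax(sizes)) + 1
    return ndimage.binary_fill_holes(labels == largest)


def shape_feature_set(mask: np.ndarray) -> dict[str, float]:
    """Region descriptors of a single-component binary mask.

    Orientation is recomputed from central moments in (x = column,
    y = row) coordinates, theta = 1/2 atan2(2 mu11, mu20 - mu02), reported in
    degrees in (-90, 90] so a horizontal structure has orientation 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    mu = props.moments_central  # indexed [row_order, col_order]
    mu20, mu02, mu11 = mu[0, 2], mu[2, 0], mu[1, 1]  # x-var, y-var, xy-cov
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    if theta <= -90.0:
        theta += 180.0
    values = (
        float(props.solidity),
        float(props.area),
        float(props.axis_major_length),
        float(props.axis_minor_length),
        float(props.area_convex),
        float(props.eccentricity),
        float(theta),
        float(props.perimeter),
        float(props.extent),
        float(props.equivalent_diameter_area),
    )
    return dict(zip(SHAPE_FEATURE_NAMES, values))


def extract_feature_vector(
    roi_image: GrayImage,
    mask: np.ndarray | None = None,
    glcm_levels: int = 8,
    glcm_distance: int = 1,
) -> dict[str, float]:
    """The full 104-feature vector for one preprocessed ROI.

    A dataset-provided lesion mask may be passed to bypass segmentation.
    Raises :class:`SegmentationError` when no mass region can be found, so a
    failing sample is flagged rather than silently zero-filled.
    """
    features = glcm_block(roi_image, glcm_distance, glcm_levels)
    features.update(histogram_feature_set(roi_image))
    if mask is None:
        mask = segment_mass_mask(roi_image)
    features.update(shape_feature_set(mask))
    assert list(features) == FEATURE_NAMES
    return features


def extract_feature_table(
    rois: list[tuple[str, GrayImage, int]],
    glcm_levels: int = 8,
    glcm_distance: int = 1,
) -> tuple[FeatureTable, list[str]]:
    """Extract features for many ``(sample_id, roi_image, label)`` triples.

    Returns the table plus the ids of samples flagged by segmentation
    failure (excluded from the table).
    """
    rows, ids, labels, flagged = [], [], [], []
    for sample_id, roi, label in rois:
        try:
            vec = extract_feature_vector(roi, None, glcm_levels, glcm_distance)
        except SegmentationError:
            flagged.append(sample_id)
            continue
        rows.append([vec[name] for name in FEATURE_NAMES])
        ids.append(sample_id)
        labels.append(label)
    if not rows:
        raise SegmentationError("every sample failed segmentation")
    return (
        FeatureTable(np.asarray(rows), list(FEATURE_NAMES), np.asarray(labels), ids),
        flagged,
    )
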