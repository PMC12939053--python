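"""Readers and writers for images, annotation records, and feature tables.

Every image entering the pipeline becomes a :class:`GrayImage`: an unsigned
integer grid with a declared bit depth, row-major, origin at the top-left
corner.  Annotation files follow the MIAS plain-text layout (one record per
line: id, tissue class, abnormality class, and — for abnormal cases —
severity, center x, center y, radius).  Feature tables travel as CSV with a
``sample_id`` column, one column per named feature, and a trailing ``label``
column (0 = benign, 1 = malignant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError


class FormatError(ValueError):
    """Raised for unsupported or unrecognized image formats."""


class CorruptFileError(IOError):
    """Raised when a raster payload is truncated or undecodable."""


class AnnotationParseError(ValueError):
    """Raised for malformed annotation lines; names the offending line."""


class SchemaError(ValueError):
    """Raised when a feature-table CSV does not match the expected schema."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with an explicit bit depth (8 or 16)."""

    pixels: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2 or pix.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if pix.min() < 0 or pix.max() > self.max_value:
            raise ValueError("pixel values outside [0, 2**bit_depth - 1]")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        object.__setattr__(self, "pixels", pix.astype(dtype, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


_SEVERITY_CODES = {"B": "benign", "M": "malignant"}


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotation line: lesion location and class for a single image.

    ``severity``/``center``/``radius`` are ``None`` for normal cases.
    Coordinates are always stored in the package's top-left, row-major
    convention.
    """

    image_id: str
    tissue_class: str
    abnormality_class: str
    severity: Optional[str] = None
    center_x: Optional[int] = None
    center_y: Optional[int] = None
    radius: Optional[int] = None

    def __post_init__(self) -> None:
        if self.severity is not None and self.severity not in ("benign", "malignant"):
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive when present")


@dataclass
class FeatureTable:
    """n samples x D named real features plus binary labels.

    The canonical pipeline output has D = 104 (see
    :data:`mammocad.features.FEATURE_NAMES`), but the container itself is
    generic: selection and classification operate on any consistent table.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match value columns")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if self.labels.shape != (n,) or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids length does not match rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_rows(self, index: Sequence[int]) -> "FeatureTable":
        index = np.asarray(index)
        return FeatureTable(
            self.values[index],
            list(self.feature_names),
            self.labels[index],
            [self.sample_ids[i] for i in index],
        )

    def select_columns(self, indices: Sequence[int]) -> "FeatureTable":
        indices = list(indices)
        return FeatureTable(
            self.values[:, indices],
            [self.feature_names[i] for i in indices],
            self.labels,
            list(self.sample_ids),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        df["label"] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        if "sample_id" not in df.columns or "label" not in df.columns:
            raise SchemaError("feature table needs 'sample_id' and 'label' columns")
        names = [c for c in df.columns if c not in ("sample_id", "label")]
        return cls(
            df[names].to_numpy(dtype=float),
            names,
            df["label"].to_numpy(),
            df["sample_id"].astype(str).tolist(),
        )


def _bit_depth_from_mode(mode: str) -> int:
    if mode == "L":
        return 8
    if mode in ("I", "I;16", "I;16B", "I;16L"):
        return 16
    raise FormatError(f"unsupported pixel mode {mode!r}; expected 8/16-bit grayscale")


def load_image(path: str | Path) -> GrayImage:
    """Load a PGM (P2/P5), PNG, or — with the ``dicom`` extra — DICOM image.

    Bit depth is inferred from the file's declared sample range (PGM maxval /
    PNG bit depth / DICOM stored bits): anything beyond 8 bits is carried as
    16-bit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _load_dicom(path)
    try:
        with Image.open(path) as im:
            bit_depth = _bit_depth_from_mode(im.mode)
            pixels = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise FormatError(f"unsupported image format: {path}") from exc
    except (OSError, SyntaxError) as exc:
        raise CorruptFileError(f"truncated or corrupt image: {path}") from exc
    if pixels.ndim != 2:
        raise FormatError(f"expected single-channel grayscale image: {path}")
    return GrayImage(pixels, bit_depth)


def _load_dicom(path: Path) -> GrayImage:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise FormatError(
            "DICOM support requires the optional 'pydicom' dependency"
        ) from exc
    ds = pydicom.dcmread(path)
    pixels = np.asarray(ds.pixel_array)
    if pixels.ndim != 2:
        raise FormatError(f"expected single-frame grayscale DICOM: {path}")
    bit_depth = 8 if int(getattr(ds, "BitsStored", 16)) <= 8 else 16
    return GrayImage(pixels, bit_depth)


def save_image(image: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as PNG (8/16-bit) or PGM (8-bit)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        Image.fromarray(image.pixels).save(path, format="PNG")
    elif suffix in (".pgm", ".ppm"):
        if image.bit_depth != 8:
            raise FormatError("PGM writing supports 8-bit images only; use PNG")
        Image.fromarray(image.pixels).save(path, format="PPM")
    else:
        raise FormatError(f"unsupported output format {suffix!r} (use .png or .pgm)")


def load_annotations(
    path: str | Path,
    origin_convention: str,
    image_height: Optional[int] = None,
) -> list[AnnotationRecord]:
    """Parse a MIAS-style annotation file.

    ``origin_convention`` must be ``"top_left"`` or ``"bottom_left"``; the
    file's own convention is not self-describing so the caller must state it.
    With ``bottom_left``, y coordinates are flipped to the package's top-left
    convention via ``y' = image_height - 1 - y`` (``image_height`` required).
    """
    if origin_convention not in ("top_left", "bottom_left"):
        raise ValueError("origin_convention must be 'top_left' or 'bottom_left'")
    if origin_convention == "bottom_left" and image_height is None:
        raise ValueError("image_height is required for bottom_left annotations")
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 3:
                raise AnnotationParseError(
                    f"line {lineno}: expected at least 3 fields, got {len(tokens)}"
                )
            image_id, tissue, abnormality = tokens[:3]
            if len(tokens) == 3:
                records.append(AnnotationRecord(image_id, tissue, abnormality))
                continue
            if len(tokens) != 7:
                raise AnnotationParseError(
                    f"line {lineno}: abnormal records need 7 fields, got {len(tokens)}"
                )
            severity = _SEVERITY_CODES.get(tokens[3])
            if severity is None:
                raise AnnotationParseError(
                    f"line {lineno}: unknown severity code {tokens[3]!r}"
                )
            try:
                x, y, radius = (int(t) for t in tokens[4:7])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {lineno}: malformed numeric field in {tokens[4:7]}"
                ) from exc
            if origin_convention == "bottom_left":
                y = image_height - 1 - y
            records.append(
                AnnotationRecord(image_id, tissue, abnormality, severity, x, y, radius)
            )
    return records


def flip_y(y: int, image_height: int) -> int:
    """Bottom-left <-> top-left y conversion (an involution)."""
    return image_height - 1 - y


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV (values kept to ~17 significant digits)."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_feature_table(
    path: str | Path, canonical_order: Optional[Sequence[str]] = None
) -> FeatureTable:
    """Read a feature-table CSV, re-ordering columns to a canonical order.

    If ``canonical_order`` is not given, the canonical 104-feature pipeline
    order is applied whenever the file's feature names match that set exactly;
    otherwise the file's own column order is kept.
    """
    df = pd.read_csv(path)
    table = FeatureTable.from_dataframe(df)
    if canonical_order is None:
        from .features import FEATURE_NAMES

        if set(table.feature_names) == set(FEATURE_NAMES):
            canonical_order = FEATURE_NAMES
    if canonical_order is not None:
        canonical_order = list(canonical_order)
        if set(canonical_order) != set(table.feature_names):
            raise SchemaError("feature names do not match the expected schema")
        index = [table.feature_names.index(name) for name in canonical_order]
        table = table.select_columns(index)
    return table


def warn_degenerate(message: str) -> None:
    warnings.warn(message, RuntimeWarning, stacklevel=3)
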