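"""Download-free synthetic data: lesion phantoms and feature tables.

Two generators exercise the pipeline end to end without any real
mammograms:

* **Mass phantoms** — a benign phantom is a smooth, compact, anti-aliased
  ellipse with mild internal texture; a malignant phantom has a radially
  jittered (Fourier-perturbed) boundary, radial spicules, and stronger
  intensity heterogeneity.  These are deliberately minimal geometric/noise
  models — no mammographic physics — but they reproduce the discriminative
  directions the real classes exhibit (solidity, boundary complexity, GLCM
  contrast/entropy), and each phantom ships with its exact generating mask
  so segmentation can be scored.
* **Feature tables** — n x D Gaussian tables with a planted informative
  subset: k columns get a between-class standardized mean difference equal
  to ``effect_size``; the remaining columns are zero-effect noise with
  optional equicorrelation.  These are the parameter-recovery harness for
  the annealing selector.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .io import FeatureTable, GrayImage, save_image
from .preprocess import ROISpec


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture of one synthetic mass image."""

    class_label: str  # "benign" or "malignant"
    image_size: int = 160
    mass_radius: float = 36.0
    axis_ratio: float = 0.85  # minor/major axis of the base ellipse
    spicule_count: int = 0
    spicule_length: float = 18.0
    spicule_width: float = 1.6
    boundary_jitter: float = 0.02  # fractional radial perturbation amplitude
    texture_noise_sd: float = 4.0
    background_noise_sd: float = 3.0
    background_level: int = 60
    mass_level: int = 170
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in ("benign", "malignant"):
            raise ValueError("class_label must be 'benign' or 'malignant'")
        if self.class_label == "benign":
            if self.spicule_count != 0:
                raise ValueError("benign phantoms have no spicules")
            if self.boundary_jitter > 0.05:
                raise ValueError("benign phantoms need boundary_jitter <= 0.05")
        reach = self.mass_radius * (1.0 + self.boundary_jitter)
        if self.spicule_count > 0:
            reach += self.spicule_length
        if reach >= self.image_size / 2 - 2:
            raise ValueError("mass (with spicules) does not fit inside the image")

    @property
    def label(self) -> int:
        return 1 if self.class_label == "malignant" else 0

    @property
    def roi(self) -> ROISpec:
        """Annotation-style crop spec covering the whole lesion."""
        reach = self.mass_radius * (1.0 + self.boundary_jitter)
        if self.spicule_count > 0:
            reach += self.spicule_length
        c = self.image_size // 2
        return ROISpec(c, c, int(np.ceil(reach)) + 4)


def benign_spec(seed: int = 0, **overrides) -> PhantomSpec:
    return PhantomSpec(class_label="benign", seed=seed, **overrides)


def malignant_spec(seed: int = 0, **overrides) -> PhantomSpec:
    defaults = dict(spicule_count=12, boundary_jitter=0.2, texture_noise_sd=18.0,
                    axis_ratio=0.75)
    defaults.update(overrides)
    return PhantomSpec(class_label="malignant", seed=seed, **defaults)


def generate_mass_image(spec: PhantomSpec) -> tuple[GrayImage, np.ndarray]:
    """Render one phantom; returns the 8-bit image and its ground-truth mask."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - c, yy - c

    # base ellipse, randomly oriented
    phi = rng.uniform(0, np.pi)
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    a = spec.mass_radius
    b = spec.mass_radius * spec.axis_ratio
    radial = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # 1.0 on the ellipse boundary

    # low-order Fourier perturbation of the boundary radius
    theta = np.arctan2(v, u)
    perturb = np.zeros_like(theta)
    if spec.boundary_jitter > 0:
        harmonics = (3, 5, 7, 9)
        amps = rng.normal(0.0, 1.0, size=len(harmonics))
        amps *= spec.boundary_jitter / (np.sqrt((amps**2).sum()) + 1e-12)
        phases = rng.uniform(0, 2 * np.pi, size=len(harmonics))
        for kk, amp, ph in zip(harmonics, amps, phases):
            perturb += amp * np.cos(kk * theta + ph)
    mask = radial <= 1.0 + perturb

    # radial spicules: line segments from the boundary outward
    if spec.spicule_count > 0:
        angles = rng.uniform(0, 2 * np.pi, size=spec.spicule_count)
        lengths = spec.spicule_length * rng.uniform(0.7, 1.3, size=spec.spicule_count)
        for ang, length in zip(angles, lengths):
            direction = np.array([np.cos(ang), np.sin(ang)])
            # boundary radius of the (unperturbed) ellipse along this direction
            ca, sa = np.cos(ang - phi), np.sin(ang - phi)
            r_boundary = 1.0 / np.sqrt((ca / a) ** 2 + (sa / b) ** 2)
            p0 = direction * (r_boundary - 1.0)
            p1 = direction * (r_boundary + length)
            # distance of every pixel to the segment p0-p1 (Gaussian-width profile)
            w = p1 - p0
            t = np.clip(((dx - p0[0]) * w[0] + (dy - p0[1]) * w[1]) / (w @ w), 0, 1)
            dist = np.hypot(dx - (p0[0] + t * w[0]), dy - (p0[1] + t * w[1]))
            mask |= dist <= spec.spicule_width

    image = rng.normal(spec.background_level, spec.background_noise_sd, (size, size))
    texture = spec.mass_level + rng.normal(0.0, spec.texture_noise_sd, (size, size))
    image[mask] = texture[mask]
    return GrayImage(np.clip(np.rint(image), 0, 255), 8), mask


def generate_phantom_dataset(
    n_per_class: int,
    benign: Optional[PhantomSpec] = None,
    malignant: Optional[PhantomSpec] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> list[tuple[str, GrayImage, np.ndarray, PhantomSpec]]:
    """Generate a balanced phantom cohort with per-sample spec perturbations.

    Each sample jitters the template radius by +-20% and the boundary jitter
    by +-30%.  Returns ``(sample_id, image, mask, spec)`` tuples; when
    ``out_dir`` is given, also writes PNG images plus a ``manifest.csv``
    (id, label, center, crop radius) consumable by the preprocessing CLI.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    benign = benign or benign_spec()
    malignant = malignant or malignant_spec()
    rng = np.random.default_rng(seed)
    samples = []
    for template in (benign, malignant):
        for i in range(n_per_class):
            radius = template.mass_radius * (1.0 + rng.uniform(-0.2, 0.2))
            jitter = template.boundary_jitter * (1.0 + rng.uniform(-0.3, 0.3))
            spec = replace(
                template,
                mass_radius=radius,
                boundary_jitter=min(jitter, 0.05) if template.label == 0 else jitter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sample_id = f"{spec.class_label[:3]}{i:03d}"
            image, mask = generate_mass_image(spec)
            samples.append((sample_id, image, mask, spec))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "label", "center_x", "center_y", "radius"])
            for sample_id, image, _, spec in samples:
                save_image(image, out_dir / f"{sample_id}.png")
                roi = spec.roi
                writer.writerow(
                    [sample_id, spec.label, roi.center_x, roi.center_y, roi.radius]
                )
    return samples


@dataclass(frozen=True)
class TableSpec:
    """A two-class Gaussian feature table with a planted informative subset."""

    n_samples: int = 200
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 2.0
    noise_correlation: float = 0.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.noise_correlation < 1:
            raise ValueError("noise_correlation must be in [0, 1)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")


def generate_feature_table(spec: TableSpec) -> tuple[FeatureTable, tuple[int, ...]]:
    """Draw the table; returns it with the informative column indices.

    Informative columns: N(0, 1) for benign rows and N(effect_size, 1) for
    malignant rows (standardized mean difference = effect_size).  Noise
    columns: zero-mean unit-variance with pairwise correlation
    ``noise_correlation`` via a shared latent factor.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples, spec.n_features, spec.n_informative
    n_pos = int(round(n * spec.class_balance))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1

    informative = tuple(sorted(rng.permutation(d)[:k].tolist()))
    values = np.empty((n, d))
    noise_cols = [i for i in range(d) if i not in informative]
    rho = spec.noise_correlation
    shared = rng.standard_normal(n)
    for col in noise_cols:
        own = rng.standard_normal(n)
        values[:, col] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    for col in informative:
        values[:, col] = rng.standard_normal(n) + spec.effect_size * labels
    names = [f"f{i:03d}" for i in range(d)]
    return FeatureTable(values, names, labels), informative
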