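"""Seeded synthetic data generators.

Images mimic the structure the pipeline assumes: a centred mid-intensity
elliptical "brain" on a dark background with additive (truncated)
Gaussian noise; positive images additionally carry 1-3 bright circular
lesion disks inside the ellipse.  The default class balance mirrors the
heavy ~9:1 positive:negative imbalance of the motivating dataset.

Feature tables are two unit-covariance Gaussian clusters whose mean
distance is ``class_separation * sqrt(dim)``.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import LabeledImageSet
from .heads import FeatureMatrix, TargetMatrix

__all__ = ["SyntheticSpec", "generate_images", "generate_feature_table"]

_BACKGROUND = 0.05
_BRAIN = 0.45
_NOISE_TRUNC_SD = 4.0  # noise clipped at +/- 4 sd: keeps lesions the only 5-sd outliers


@dataclass(frozen=True)
class SyntheticSpec:
    n_pos: int = 177
    n_neg: int = 20
    image_size: int = 256
    lesion_radius_range: tuple = (8, 20)
    lesion_contrast: float = 0.5
    background_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class counts must be non-negative")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < self.image_size // 2):
            raise ValueError("invalid lesion radius range")
        if self.lesion_contrast <= 0:
            raise ValueError("lesion_contrast must be positive")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")
        if self.lesion_contrast <= self.background_noise_sd:
            raise ValueError("lesion_contrast must exceed background_noise_sd")


def _ellipse_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    ay, ax = 0.40 * size, 0.32 * size
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _one_image(size: int, brain: np.ndarray, lesion_spec, noise_sd: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    img = np.full((size, size), _BACKGROUND)
    img[brain] = _BRAIN
    lesion_mask = np.zeros((size, size), dtype=bool)
    if lesion_spec is not None:
        r_lo, r_hi, contrast = lesion_spec
        yy, xx = np.mgrid[0:size, 0:size]
        cy = cx = (size - 1) / 2.0
        for _ in range(int(rng.integers(1, 4))):
            radius = float(rng.uniform(r_lo, r_hi))
            # sample the centre well inside the ellipse so the disk stays inside
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(0, 1)) * 0.6
            ly = cy + rad * 0.40 * size * np.sin(ang)
            lx = cx + rad * 0.32 * size * np.cos(ang)
            disk = (yy - ly) ** 2 + (xx - lx) ** 2 <= radius**2
            lesion_mask |= disk & brain
        img[lesion_mask] += contrast
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(size, size))
        limit = _NOISE_TRUNC_SD * noise_sd
        img = img + np.clip(noise, -limit, limit)
    return np.clip(img, 0.0, 1.0), lesion_mask


def generate_images(spec: SyntheticSpec) -> LabeledImageSet:
    """Generate a labeled synthetic image set (positives first).

    Deterministic per spec; lesion ground-truth masks are attached as
    ``lesion_masks`` (all-False for negatives).
    """
    if spec.n_pos + spec.n_neg < 2:
        raise ValueError("need at least 2 images in total")
    rng = np.random.default_rng(spec.seed)
    brain = _ellipse_mask(spec.image_size)
    lo, hi = spec.lesion_radius_range
    images, labels, ids, masks = [], [], [], []
    for i in range(spec.n_pos):
        img, mask = _one_image(spec.image_size, brain, (lo, hi, spec.lesion_contrast),
                               spec.background_noise_sd, rng)
        images.append(img)
        labels.append(1)
        ids.append(f"pos_{i:04d}")
        masks.append(mask)
    for i in range(spec.n_neg):
        img, mask = _one_image(spec.image_size, brain, None,
                               spec.background_noise_sd, rng)
        images.append(img)
        labels.append(0)
        ids.append(f"neg_{i:04d}")
        masks.append(mask)
    return LabeledImageSet(images=images, labels=np.array(labels), ids=ids,
                           lesion_masks=masks)


def generate_feature_table(n_pos: int, n_neg: int, dim: int, class_separation: float,
                           seed: int) -> tuple[FeatureMatrix, TargetMatrix]:
    """Two Gaussian clusters with mean distance class_separation*sqrt(dim).

    Rows are positives first (one-hot column 1), then negatives (column 0);
    unit covariance in every coordinate.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be >= 1")
    if class_separation < 0:
        raise ValueError("class_separation must be non-negative")
    rng = np.random.default_rng(seed)
    half = class_separation / 2.0
    pos = rng.normal(half, 1.0, size=(n_pos, dim))
    neg = rng.normal(-half, 1.0, size=(n_neg, dim))
    X = FeatureMatrix(np.vstack([pos, neg]))
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return X, TargetMatrix.from_labels(labels, m=2)
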