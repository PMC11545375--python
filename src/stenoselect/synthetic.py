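"""Synthetic data: planted-feature tables and vessel-like angiogram patches.

Two generators make every other module testable without the external image
database:

* :func:`make_feature_dataset` builds a balanced binary-labeled table in
  which a known minority of columns carry a Gaussian class shift (the
  planted informative subset), optionally with correlated redundant copies,
  amid independent noise columns.  The Gaussian shift model is chosen for
  its analytically known Bayes error, not for realism.

* :func:`make_vessel_patch` draws a dark curvilinear "vessel" (a tube of
  configurable width around a quadratic arc) on a brighter noisy
  background, optionally with a local narrowing at mid-arc emulating a
  stenosis.  Vessels are darker than the background, matching X-ray
  angiography.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GrayImage, LabeledDataset

__all__ = [
    "SyntheticSpec",
    "make_feature_dataset",
    "make_vessel_patch",
    "make_patch_bank",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 200
    n_features: int = 30
    n_informative: int = 5
    effect_size: float = 2.0  # standardized mean shift between classes
    n_redundant: int = 0
    noise_sd: float = 0.5  # jitter of redundant copies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ValueError("need at least 2 samples and 1 feature")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("informative + redundant must not exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


def make_feature_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, np.ndarray]:
    """Generate a labeled table with a planted informative feature subset.

    Returns the dataset and a truth mask marking the informative columns.
    Labels are balanced; informative columns are N(+-effect_size/2, 1) by
    class, redundant columns are informative columns plus N(0, noise_sd),
    the rest are N(0, 1) independent of the label.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    labels = np.zeros(n, dtype=np.int64)
    labels[: n // 2] = 1
    labels = rng.permutation(labels)
    X = rng.standard_normal((n, d))
    shift = np.where(labels == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)
    for j in range(spec.n_informative):
        X[:, j] += shift
    for k in range(spec.n_redundant):
        src = k % max(spec.n_informative, 1)
        X[:, spec.n_informative + k] = X[:, src] + rng.normal(0.0, spec.noise_sd, n)
    truth = np.zeros(d, dtype=np.uint8)
    truth[: spec.n_informative] = 1
    names = [f"feature_{j:03d}" for j in range(d)]
    return LabeledDataset(X, labels, names), truth


def make_vessel_patch(
    size: int = 64,
    width: float = 7.0,
    curvature: float = 0.3,
    narrowing: float = 0.0,
    noise_sd: float = 8.0,
    seed: int = 0,
    background: float = 170.0,
    vessel_depth: float = 90.0,
) -> tuple[GrayImage, np.ndarray]:
    """A dark tube along a quadratic arc on a noisy brighter background.

    ``narrowing`` in [0, 1) shrinks the tube width at mid-arc by that
    fraction (a stenosis-like local width reduction).  Returns the image and
    the ground-truth centerline mask.
    """
    if width < 1:
        raise ValueError("width must be >= 1 px")
    if size < 16:
        raise ValueError("size must be >= 16 px")
    if not 0.0 <= narrowing < 1.0:
        raise ValueError("narrowing must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    margin = max(3.0, width)
    t = np.linspace(0.0, 1.0, 6 * size)
    cx = margin + t * (size - 1 - 2 * margin)  # column coordinate
    cy = size / 2.0 + curvature * size * ((t - 0.5) ** 2 - 0.125)  # row coordinate
    half_w = 0.5 * width * (1.0 - narrowing * np.exp(-(((t - 0.5) / 0.12) ** 2)))
    if (cy - half_w).min() < 0 or (cy + half_w).max() > size - 1:
        raise ValueError("tube exits the frame; reduce curvature or width")

    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    px = np.stack([rows.ravel(), cols.ravel()], axis=1)  # (size^2, 2)
    center = np.stack([cy, cx], axis=1)  # (m, 2)
    d2 = ((px[:, None, :] - center[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(px.shape[0]), nearest])
    local_half = half_w[nearest]
    vessel = (dist <= local_half).reshape(size, size)

    image = np.full((size, size), background, dtype=np.float64)
    image[vessel] -= vessel_depth
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, image.shape)
    pixels = np.clip(np.rint(image), 0, 255).astype(np.int64)

    centerline = np.zeros((size, size), dtype=bool)
    centerline[np.clip(np.rint(cy).astype(int), 0, size - 1),
               np.clip(np.rint(cx).astype(int), 0, size - 1)] = True
    return GrayImage(pixels, maxval=255), centerline


def make_patch_bank(
    n: int,
    positive_fraction: float = 0.5,
    seed: int = 0,
    size: int = 64,
    width_range: tuple[float, float] = (5.0, 9.0),
    curvature_range: tuple[float, float] = (0.0, 0.5),
    narrowing_range: tuple[float, float] = (0.3, 0.7),
    noise_sd: float = 8.0,
) -> tuple[list[GrayImage], np.ndarray]:
    """A bank of vessel patches: positives carry a mid-arc narrowing.

    Widths, curvatures and noise are randomized identically for both classes,
    so the narrowing is the only systematic difference.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * positive_fraction))
    labels = np.zeros(n, dtype=np.int64)
    labels[:n_pos] = 1
    labels = rng.permutation(labels)
    images: list[GrayImage] = []
    for label in labels:
        width = rng.uniform(*width_range)
        curvature = rng.uniform(*curvature_range)
        narrowing = rng.uniform(*narrowing_range) if label == 1 else 0.0
        patch_seed = int(rng.integers(2**31 - 1))
        img, _ = make_vessel_patch(
            size=size,
            width=width,
            curvature=curvature,
            narrowing=narrowing,
            noise_sd=noise_sd,
            seed=patch_seed,
        )
        images.append(img)
    return images, labels
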