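"""Synthetic endoscopy-like frames and planted-feature tables.

The frame generator emulates the visual ingredients the pipeline's
preprocessing targets: a mucosa-toned textured background, elliptical
lesions with a class-dependent color/contrast shift, bright specular
"bubble" discs, and an additive white haze veil. Ground-truth lesion
masks come straight from the generating ellipses, so segmentation can
be scored against an exact reference.

The table generator plants ``k`` informative Gaussian dimensions
(class-dependent means, separation measured in noise-sd units) among
pure-noise columns, the standard benchmark for wrapper feature
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["FrameRecipe", "TableRecipe", "make_frames", "make_table"]

# luminance-asymmetric color shifts per lesion class (unit contrast)
_CLASS_SHIFTS = [
    np.array([-1.0, -0.70, -0.55]),   # dark reddish ulcer-like lesion
    np.array([1.0, 0.90, 0.35]),      # bright yellowish polyp-like lesion
    np.array([-0.35, -1.0, -0.90]),   # desaturated greenish-dark lesion
    np.array([0.45, -0.70, 0.95]),    # violet-shifted lesion
]


@dataclass
class FrameRecipe:
    """Parameters of one batch of synthetic frames.

    size : frame side in pixels (frames are square).
    n_frames : number of frames to generate.
    n_classes : number of lesion classes; frames are assigned round-robin.
    base_color : mucosa base RGB.
    texture_scale : amplitude of the smoothed value-noise texture.
    texture_length : correlation length (px) of the texture.
    lesion_count : lesions per frame.
    lesion_radius : (min, max) semi-axis range in pixels.
    lesion_contrast : luminance-scale contrast shift of lesions.
    bubble_count / bubble_radius / bubble_brightness : specular discs.
    haze : weight of the additive white veil.
    seed : generator seed.
    """

    size: int = 96
    n_frames: int = 10
    n_classes: int = 2
    base_color: tuple[float, float, float] = (0.70, 0.42, 0.38)
    texture_scale: float = 0.035
    texture_length: float = 6.0
    lesion_count: int = 1
    lesion_radius: tuple[int, int] = (12, 20)
    lesion_contrast: float = 0.30
    bubble_count: int = 3
    bubble_radius: tuple[int, int] = (2, 5)
    bubble_brightness: float = 0.95
    haze: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.lesion_count < 0 or self.bubble_count < 0:
            raise ValueError("counts must be >= 0")
        if self.n_classes < 1 or self.n_classes > len(_CLASS_SHIFTS):
            raise ValueError(f"n_classes must be in [1, {len(_CLASS_SHIFTS)}]")
        if 2 * self.lesion_radius[1] >= self.size:
            raise ValueError("lesion larger than the frame")
        if not 0.0 <= self.haze < 1.0:
            raise ValueError("haze must be in [0, 1)")


@dataclass
class TableRecipe:
    """Parameters of a planted-feature classification table."""

    n: int = 200
    d: int = 50
    k: int = 5
    effect: float = 2.0
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.k > self.d:
            raise ValueError("k informative columns cannot exceed d")
        if self.n < 2 * self.n_classes:
            raise ValueError("need at least two samples per class")


def _texture(rng: np.random.Generator, size: int, length: float, scale: float) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=length, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return smooth * scale


def _ellipse_mask_and_weight(size, center, axes, angle):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / axes[1]
    v = (-sa * dx + ca * dy) / axes[0]
    d2 = u * u + v * v
    mask = d2 <= 1.0
    weight = np.clip((1.0 - d2) / 0.25, 0.0, 1.0)  # soft rim, solid interior
    return mask, weight


def make_frames(recipe: FrameRecipe) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate frames, exact lesion masks and class labels.

    Returns ``(images, masks, labels)`` with shapes
    (n, size, size, 3), (n, size, size) boolean, (n,) int. The label of
    a frame is its lesion class (0-based); with ``lesion_count == 0``
    every label is 0 and masks are empty.
    """
    rng = np.random.default_rng(recipe.seed)
    size = recipe.size
    images, masks, labels = [], [], []
    margin = recipe.lesion_radius[1] + 2
    for i in range(recipe.n_frames):
        cls = i % recipe.n_classes
        img = np.empty((size, size, 3))
        base = np.asarray(recipe.base_color)
        tex = _texture(rng, size, recipe.texture_length, recipe.texture_scale)
        fine = rng.standard_normal((size, size)) * recipe.texture_scale * 0.25
        for c in range(3):
            img[:, :, c] = base[c] + tex * (0.8 + 0.4 * c / 2.0) + fine
        mask = np.zeros((size, size), dtype=bool)
        shift = _CLASS_SHIFTS[cls] * recipe.lesion_contrast
        for _ in range(recipe.lesion_count):
            center = rng.uniform(margin, size - margin, size=2)
            axes = rng.uniform(*recipe.lesion_radius, size=2)
            angle = rng.uniform(0, np.pi)
            m, w = _ellipse_mask_and_weight(size, center, axes, angle)
            img += w[:, :, None] * shift[None, None, :]
            mask |= m
        for _ in range(recipe.bubble_count):
            # specular bubbles sit on clean mucosa, never on the lesion,
            # so the ground-truth mask keeps its full contrast
            for _attempt in range(20):
                center = rng.uniform(3, size - 3, size=2)
                radius = rng.uniform(*recipe.bubble_radius)
                if not mask[int(center[0]), int(center[1])]:
                    break
            m, w = _ellipse_mask_and_weight(size, center, (radius, radius), 0.0)
            w = np.where(mask, 0.0, w)
            img = img * (1 - w[:, :, None]) + w[:, :, None] * recipe.bubble_brightness
        img = (1 - recipe.haze) * img + recipe.haze * 1.0
        img = np.clip(img, 0.0, 1.0)
        if recipe.lesion_count and recipe.lesion_contrast >= 0.2:
            # generator self-check: lesions must actually be visible
            gray = img.mean(axis=2)
            gap = abs(gray[mask].mean() - gray[~mask].mean())
            assert gap >= 0.4 * recipe.lesion_contrast, "lesion contrast self-check failed"
        images.append(img)
        masks.append(mask)
        labels.append(cls)
    return np.stack(images), np.stack(masks), np.asarray(labels, dtype=int)


def make_table(recipe: TableRecipe) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a planted-feature table.

    Returns ``(X, y, informative_idx)``: an (n, d) matrix whose
    ``informative_idx`` columns have class-conditional means separated
    by ``effect`` noise standard deviations, all other columns pure
    standard normal noise.
    """
    rng = np.random.default_rng(recipe.seed)
    x = rng.standard_normal((recipe.n, recipe.d))
    y = np.arange(recipe.n) % recipe.n_classes
    y = rng.permutation(y)
    informative = rng.choice(recipe.d, size=recipe.k, replace=False)
    informative.sort()
    # class centers on a simplex-like grid, pairwise distance = effect per axis
    signs = rng.choice([-1.0, 1.0], size=recipe.k)
    for j, col in enumerate(informative):
        centers = (np.arange(recipe.n_classes) - (recipe.n_classes - 1) / 2.0) * recipe.effect
        x[:, col] += signs[j] * centers[y]
    return x, y, informative
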