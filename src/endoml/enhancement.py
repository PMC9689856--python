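"""Hybrid sequential-fusion contrast enhancement for endoscopy frames.

The chain is: per-channel denoising (bubble/speckle suppression),
white top-hat and black bottom-hat filtering to pull out small bright
and dark structures, an arithmetic fusion with the original frame,
dark-channel-prior dehazing to strip the white veil that capsule
optics add, and a final multiplicative/additive fusion that boosts
the lesion-to-mucosa contrast.

All images are H x W x 3 float arrays in [0, 1]; intermediate stages
that can leave that range are clamped back so every stage output is
itself a valid image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.restoration import denoise_nl_means
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EnhancementConfig",
    "ContrastEnhancer",
    "split_channels",
    "denoise_channels",
    "top_bottom_hat",
    "fuse_hat",
    "dehaze",
    "fuse_final",
    "enhance",
]

_DENOISERS = ("identity", "median", "nlm")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return img


@dataclass
class EnhancementConfig:
    """Free parameters of the enhancement chain.

    selem_radius : disk radius (px) of the top/bottom-hat structuring
        element; ~5 at 256x256 matches the vessel/bubble scale.
    denoiser : one of {"identity", "median", "nlm"}; "median" is the
        default bubble/speckle suppressor.
    dehaze_patch : side of the dark-channel erosion window.
    dehaze_omega : fraction of the estimated veil removed.
    dehaze_t0 : transmission floor guarding the division.
    subtract_denoised : when True Eq-style hat fusion subtracts the
        denoised frame instead of the original.
    """

    selem_radius: int = 5
    denoiser: str = "median"
    dehaze_patch: int = 15
    dehaze_omega: float = 0.95
    dehaze_t0: float = 0.1
    subtract_denoised: bool = False

    def __post_init__(self):
        if self.selem_radius < 1:
            raise ValueError("selem_radius must be >= 1")
        if self.denoiser not in _DENOISERS:
            raise ValueError(f"denoiser must be one of {_DENOISERS}")
        if not (self.dehaze_patch >= 1 and self.dehaze_patch % 2 == 1):
            raise ValueError("dehaze_patch must be an odd positive integer")
        if not 0.0 <= self.dehaze_omega <= 1.0:
            raise ValueError("dehaze_omega must be in [0, 1]")
        if not 0.0 < self.dehaze_t0 <= 1.0:
            raise ValueError("dehaze_t0 must be in (0, 1]")


def split_channels(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB frame into its three planes c1, c2, c3."""
    img = _check_image(img)
    return img[:, :, 0].copy(), img[:, :, 1].copy(), img[:, :, 2].copy()


def _denoise_plane(plane: np.ndarray, denoiser: str) -> np.ndarray:
    if denoiser == "identity":
        return plane.copy()
    if denoiser == "median":
        return ndimage.median_filter(plane, size=3, mode="reflect")
    if denoiser == "nlm":
        return denoise_nl_means(plane, patch_size=5, patch_distance=6, h=0.08)
    raise ValueError(f"unknown denoiser {denoiser!r}")


def denoise_channels(
    channels: tuple[np.ndarray, np.ndarray, np.ndarray], denoiser: str = "median"
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], np.ndarray]:
    """Denoise each plane; returns (f1, f2, f3) and their stack f4."""
    c1, c2, c3 = (np.asarray(c, dtype=float) for c in channels)
    if not (c1.shape == c2.shape == c3.shape) or c1.ndim != 2:
        raise ValueError("channels must be three 2-D planes of identical shape")
    f1, f2, f3 = (_denoise_plane(c, denoiser) for c in (c1, c2, c3))
    f4 = np.stack([f1, f2, f3], axis=2)
    return (f1, f2, f3), f4


def top_bottom_hat(img: np.ndarray, selem_radius: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel white top-hat and black bottom-hat transforms.

    top-hat = img - opening(img), bottom-hat = closing(img) - img;
    both are non-negative by construction.
    """
    img = _check_image(img)
    if selem_radius < 1:
        raise ValueError("structuring element radius must be >= 1")
    if selem_radius >= min(img.shape[:2]) / 2:
        raise ValueError("structuring element too large for the image")
    footprint = disk(selem_radius).astype(bool)
    top = np.empty_like(img)
    bot = np.empty_like(img)
    for c in range(3):
        plane = img[:, :, c]
        opened = ndimage.grey_dilation(
            ndimage.grey_erosion(plane, footprint=footprint, mode="reflect"),
            footprint=footprint,
            mode="reflect",
        )
        closed = ndimage.grey_erosion(
            ndimage.grey_dilation(plane, footprint=footprint, mode="reflect"),
            footprint=footprint,
            mode="reflect",
        )
        top[:, :, c] = plane - opened
        bot[:, :, c] = closed - plane
    return top, bot


def fuse_hat(top: np.ndarray, bot: np.ndarray, original: np.ndarray) -> np.ndarray:
    """(top + bottom) - original, clamped to [0, 1]."""
    top, bot, original = (np.asarray(a, dtype=float) for a in (top, bot, original))
    if not (top.shape == bot.shape == original.shape):
        raise ValueError("hat images and original must share a shape")
    return np.clip(top + bot - original, 0.0, 1.0)


def _dark_channel(img: np.ndarray, patch: int) -> np.ndarray:
    return ndimage.minimum_filter(img.min(axis=2), size=patch, mode="reflect")


def dehaze(
    img: np.ndarray, patch: int = 15, omega: float = 0.95, t0: float = 0.1
) -> np.ndarray:
    """Dark-channel-prior single-image dehazing.

    Atmospheric light A is the mean color of the brightest 0.1% of
    pixels ranked by the dark channel; the transmission estimate is
    1 - omega * darkchannel(img / A), floored at t0, and the scene is
    recovered as (img - A) / t + A, clamped to [0, 1].
    """
    img = _check_image(img)
    dark = _dark_channel(img, patch)
    n = dark.size
    k = max(1, int(np.ceil(n * 0.001)))
    flat_idx = np.argpartition(dark.ravel(), n - k)[n - k :]
    rows, cols = np.unravel_index(flat_idx, dark.shape)
    a = img[rows, cols].mean(axis=0)
    a = np.maximum(a, 1e-6)
    normed = np.clip(img / a[None, None, :], 0.0, 1.0)
    transmission = 1.0 - omega * _dark_channel(normed, patch)
    transmission = np.maximum(transmission, t0)
    out = (img - a[None, None, :]) / transmission[:, :, None] + a[None, None, :]
    return np.clip(out, 0.0, 1.0)


def fuse_final(hz: np.ndarray, fused: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Final fusion: clamp(hz * (fused * top) + hz)."""
    hz, fused, top = (np.asarray(a, dtype=float) for a in (hz, fused, top))
    if not (hz.shape == fused.shape == top.shape):
        raise ValueError("fusion inputs must share a shape")
    nw = fused * top
    ml = hz * nw
    return np.clip(ml + hz, 0.0, 1.0)


def enhance(img: np.ndarray, cfg: EnhancementConfig | None = None) -> np.ndarray:
    """Run the full enhancement chain on one frame."""
    cfg = cfg or EnhancementConfig()
    img = _check_image(img)
    channels = split_channels(img)
    _, f4 = denoise_channels(channels, cfg.denoiser)
    top, bot = top_bottom_hat(f4, cfg.selem_radius)
    reference = f4 if cfg.subtract_denoised else img
    fused = fuse_hat(top, bot, reference)
    hz = dehaze(fused, cfg.dehaze_patch, cfg.dehaze_omega, cfg.dehaze_t0)
    return fuse_final(hz, fused, top)


class ContrastEnhancer(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer over stacks of RGB frames.

    ``transform`` accepts a single H x W x 3 frame or an
    N x H x W x 3 stack and applies :func:`enhance` to each frame.
    """

    def __init__(self, selem_radius=5, denoiser="median", dehaze_patch=15,
                 dehaze_omega=0.95, dehaze_t0=0.1, subtract_denoised=False):
        self.selem_radius = selem_radius
        self.denoiser = denoiser
        self.dehaze_patch = dehaze_patch
        self.dehaze_omega = dehaze_omega
        self.dehaze_t0 = dehaze_t0
        self.subtract_denoised = subtract_denoised

    def _config(self) -> EnhancementConfig:
        return EnhancementConfig(
            selem_radius=self.selem_radius,
            denoiser=self.denoiser,
            dehaze_patch=self.dehaze_patch,
            dehaze_omega=self.dehaze_omega,
            dehaze_t0=self.dehaze_t0,
            subtract_denoised=self.subtract_denoised,
        )

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return enhance(X, cfg)
        if X.ndim == 4:
            return np.stack([enhance(frame, cfg) for frame in X])
        raise ValueError("expected an image or a stack of images")
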