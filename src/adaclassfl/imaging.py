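"""Image preparation for leaf-disease classification.

Two distinct stages share this module:

* **Preprocessing** — deterministic, applied identically at train and
  inference time: contrast-limited adaptive histogram equalization (CLAHE),
  gamma brightening (gamma = 1.2 maps v to 255*(v/255)^(1/gamma), lifting
  dim field imagery), and bilateral or Gaussian denoising, in that order.
* **Augmentation** — stochastic, train-only: horizontal/vertical flips,
  bounded rotation, small affine jitter, color jitter, and edge sharpening,
  each gated independently with probability ``p`` from a caller-supplied
  generator.

CLAHE is implemented here with clip-limit semantics (per-tile histograms,
uniform redistribution of clipped excess, midpoint-CDF lookup tables,
bilinear interpolation between tile mappings).  A spatially constant image
stays spatially constant; mid-range constant values are preserved exactly,
extreme values may shift by a gray level or two — the unavoidable bias of
clipped equalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.restoration import denoise_bilateral
from skimage.transform import AffineTransform, rotate, warp

__all__ = ["PreprocessConfig", "AugmentConfig", "preprocess", "augment",
           "clahe", "gamma_correct"]


@dataclass(frozen=True)
class PreprocessConfig:
    clahe_clip: float = 2.0
    clahe_tile: int = 8
    gamma: float = 1.2
    denoise: str = "bilateral"          # or "gaussian"

    def validate(self) -> None:
        if self.clahe_clip <= 0 or self.gamma <= 0:
            raise ValueError("clahe_clip and gamma must be positive")
        if self.clahe_tile < 1:
            raise ValueError("clahe_tile must be >= 1")
        if self.denoise not in ("bilateral", "gaussian"):
            raise ValueError("denoise must be 'bilateral' or 'gaussian'")


@dataclass(frozen=True)
class AugmentConfig:
    p: float = 0.5
    rotation_limit: float = 15.0
    affine_limit: float = 0.1           # max |translate| fraction and scale jitter
    jitter: float = 0.2                 # +-20% brightness/contrast/saturation
    sharpen_strength: float = 1.5

    def validate(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.rotation_limit < 0 or self.affine_limit < 0 or self.jitter < 0:
            raise ValueError("limits must be non-negative")


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB (H, W, 3) image")


# ---------------------------------------------------------------------------
# CLAHE

def _tile_lut(channel_tile: np.ndarray, clip: float) -> np.ndarray:
    """Midpoint-CDF lookup table (float, 256 entries) for one tile."""
    area = channel_tile.size
    hist = np.bincount(channel_tile.ravel(), minlength=256).astype(float)
    limit = clip * area / 256.0
    excess = np.maximum(hist - limit, 0.0).sum()
    hist = np.minimum(hist, limit) + excess / 256.0
    cdf = np.cumsum(hist)
    mid = cdf - hist / 2.0
    return 255.0 * mid / area


def clahe(channel: np.ndarray, clip: float = 2.0, tile: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one uint8 channel.

    The tile grid is clamped so every tile spans at least 8 pixels per side
    (small images fall back toward a single global histogram).
    """
    h, w = channel.shape
    gy = max(1, min(tile, h // 8))
    gx = max(1, min(tile, w // 8))
    y_edges = np.linspace(0, h, gy + 1).astype(int)
    x_edges = np.linspace(0, w, gx + 1).astype(int)
    luts = np.empty((gy, gx, 256))
    cy = np.empty(gy)
    cx = np.empty(gx)
    for i in range(gy):
        cy[i] = (y_edges[i] + y_edges[i + 1] - 1) / 2.0
        for j in range(gx):
            cx[j] = (x_edges[j] + x_edges[j + 1] - 1) / 2.0
            luts[i, j] = _tile_lut(channel[y_edges[i]:y_edges[i + 1],
                                           x_edges[j]:x_edges[j + 1]], clip)
    # bilinear interpolation between the four surrounding tile mappings
    yy = np.arange(h, dtype=float)
    xx = np.arange(w, dtype=float)
    iy = np.clip(np.searchsorted(cy, yy) - 1, 0, max(gy - 2, 0))
    ix = np.clip(np.searchsorted(cx, xx) - 1, 0, max(gx - 2, 0))
    if gy > 1:
        ty = np.clip((yy - cy[iy]) / (cy[iy + 1] - cy[iy]), 0.0, 1.0)
    else:
        ty = np.zeros(h)
    if gx > 1:
        tx = np.clip((xx - cx[ix]) / (cx[ix + 1] - cx[ix]), 0.0, 1.0)
    else:
        tx = np.zeros(w)
    v = channel.astype(int)
    iy2 = np.minimum(iy + 1, gy - 1)
    ix2 = np.minimum(ix + 1, gx - 1)
    IY, IX = np.meshgrid(iy, ix, indexing="ij")
    IY2, IX2 = np.meshgrid(iy2, ix2, indexing="ij")
    TY = ty[:, None]
    TX = tx[None, :]
    out = ((1 - TY) * (1 - TX) * luts[IY, IX, v]
           + (1 - TY) * TX * luts[IY, IX2, v]
           + TY * (1 - TX) * luts[IY2, IX, v]
           + TY * TX * luts[IY2, IX2, v])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Brightening gamma map v -> 255 * (v/255)^(1/gamma) via a uint8 LUT."""
    lut = np.clip(np.rint(255.0 * (np.arange(256) / 255.0) ** (1.0 / gamma)),
                  0, 255).astype(np.uint8)
    return lut[image]


def preprocess(image: np.ndarray, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """CLAHE -> gamma correction -> denoise; deterministic, dtype-preserving."""
    config.validate()
    _check_rgb(image)
    out = np.stack([clahe(image[..., c], config.clahe_clip, config.clahe_tile)
                    for c in range(3)], axis=-1)
    out = gamma_correct(out, config.gamma)
    if config.denoise == "gaussian":
        sm = np.stack([gaussian_filter(out[..., c].astype(float), sigma=1.0)
                       for c in range(3)], axis=-1)
    else:
        sm = denoise_bilateral(out.astype(np.float64) / 255.0,
                               sigma_color=0.1, sigma_spatial=2.0,
                               channel_axis=-1) * 255.0
    return np.clip(np.rint(sm), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# train-only augmentation

def _sharpen(img: np.ndarray, strength: float) -> np.ndarray:
    f = img.astype(float)
    blur = np.stack([gaussian_filter(f[..., c], sigma=1.0) for c in range(3)],
                    axis=-1)
    return f + strength * (f - blur)


def augment(image: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Apply each transform independently with probability ``config.p``.

    Draw order is fixed (gate draw, then the op's own parameter draws), so a
    given generator state always yields the same augmented image: horizontal
    flip, vertical flip, rotation, affine, color jitter, sharpening.
    """
    config.validate()
    _check_rgb(image)
    out = image.astype(float)

    if rng.random() < config.p:
        out = out[:, ::-1, :]
    if rng.random() < config.p:
        out = out[::-1, :, :]
    if rng.random() < config.p:
        angle = rng.uniform(-config.rotation_limit, config.rotation_limit)
        if angle != 0.0:
            out = rotate(out, angle, preserve_range=True, mode="edge")
    if rng.random() < config.p:
        ty_, tx_ = rng.uniform(-config.affine_limit, config.affine_limit, 2)
        scale = 1.0 + rng.uniform(-config.affine_limit, config.affine_limit)
        if (ty_, tx_, scale) != (0.0, 0.0, 1.0):
            h, w = out.shape[:2]
            tf = AffineTransform(scale=scale,
                                 translation=(tx_ * w, ty_ * h))
            out = warp(out, tf.inverse, preserve_range=True, mode="edge")
    if rng.random() < config.p:
        fb = 1.0 + rng.uniform(-config.jitter, config.jitter)
        fc = 1.0 + rng.uniform(-config.jitter, config.jitter)
        fs = 1.0 + rng.uniform(-config.jitter, config.jitter)
        out = out * fb
        mean = out.mean()
        out = mean + fc * (out - mean)
        gray = out.mean(axis=-1, keepdims=True)
        out = gray + fs * (out - gray)
    if rng.random() < config.p:
        out = _sharpen(np.clip(out, 0, 255), config.sharpen_strength)

    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
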