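"""Image preparation: [-1, 1] normalization, histogram equalization,
block-average downsampling, and rough tissue/background segmentation.

These steps mirror the acquisition-side conditioning the networks expect:
every image entering a model is affinely mapped onto [-1, 1]; RGB frames are
globally equalized on luminance only (hue is diagnostic of serosa state and
must not move); high-resolution frames are reduced by block averaging; and a
parameter-free Otsu binarization of the RGB separates tissue from the
background so residual maps can be masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, filters, measure

from ischemap.errors import DimensionError, ValidationError


@dataclass
class NormalizedImage:
    """Values in [-1, 1] plus the original (min, max) for exact inversion."""

    values: np.ndarray
    original_range: tuple

    def denormalize(self) -> np.ndarray:
        lo, hi = self.original_range
        return (self.values + 1.0) * (0.5 * (hi - lo)) + lo


@dataclass
class TissueMask:
    values: np.ndarray            # binary, 1 = tissue
    method: str = "otsu-rgb"

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)


def normalize(image: np.ndarray) -> NormalizedImage:
    """Affine map of [min, max] onto [-1, 1]."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi - lo <= 0:
        raise ValidationError("cannot normalize a constant image")
    # divide before scaling so the endpoints map to exactly -1 and +1
    values = (image - lo) / (hi - lo) * 2.0 - 1.0
    return NormalizedImage(values, (lo, hi))


def denormalize(norm: NormalizedImage) -> np.ndarray:
    return norm.denormalize()


def equalize_histogram(rgb: np.ndarray) -> np.ndarray:
    """Global histogram equalization on the luminance channel only.

    The image is converted to YCbCr, Y is equalized, chrominance passes
    through unchanged.  A constant image is returned untouched.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise DimensionError("expected an (H, W, 3) image")
    ycbcr = color.rgb2ycbcr(rgb)
    y = ycbcr[..., 0]
    if y.max() - y.min() <= 0:
        return rgb.copy()
    # equalize Y on its native 16..235 excursion
    y01 = (y - 16.0) / 219.0
    from skimage import exposure

    y_eq = exposure.equalize_hist(y01) * 219.0 + 16.0
    out = ycbcr.copy()
    out[..., 0] = y_eq
    return np.clip(color.ycbcr2rgb(out), 0.0, 1.0)


def downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Anti-aliased block-average reduction by an integer factor."""
    image = np.asarray(image, dtype=np.float64)
    if factor < 1:
        raise ValidationError("factor must be a positive integer")
    h, w = image.shape[:2]
    if h % factor or w % factor:
        raise ValidationError(
            f"image {h}x{w} not divisible by factor {factor}")
    if image.ndim == 2:
        return image.reshape(h // factor, factor, w // factor, factor).mean(
            axis=(1, 3))
    c = image.shape[2]
    return image.reshape(h // factor, factor, w // factor, factor, c).mean(
        axis=(1, 3))


def segment_tissue(rgb: np.ndarray) -> TissueMask:
    """Rough tissue/background separation by Otsu on a color-distance score.

    The background color is estimated from the image border; each pixel's
    Euclidean distance (in RGB) to that color is thresholded by Otsu and the
    largest connected component is kept as tissue.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise DimensionError("expected an (H, W, 3) image")
    border = np.concatenate([
        rgb[0].reshape(-1, 3), rgb[-1].reshape(-1, 3),
        rgb[:, 0].reshape(-1, 3), rgb[:, -1].reshape(-1, 3)])
    bg = np.median(border, axis=0)
    score = np.sqrt(((rgb - bg) ** 2).sum(axis=2))
    if score.max() - score.min() <= 1e-12:
        raise ValidationError("constant image: no separable classes")
    thr = filters.threshold_otsu(score)
    mask = score > thr
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValidationError("no foreground found")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return TissueMask(labels == largest, method="otsu-rgb")
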