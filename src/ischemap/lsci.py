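"""Laser speckle contrast imaging core.

Speckle contrast is the ratio K = σ/⟨I⟩ of the intensity standard deviation
to the mean intensity over a small window.  Moving scatterers (red blood
cells) blur the speckle pattern within the exposure, lowering K, so K maps
inversely onto perfusion: the relative flow index used throughout the
pipeline is 1/K².  Fully developed static speckle has K = 1.

Windows may be spatial (the pipeline default, 5×5), temporal, or both.  The
standard deviation is the population estimator (ddof = 0) over the window,
borders are handled by reflection padding, and K is defined as 0 wherever
the local mean falls below ``eps`` (dark background must not masquerade as
flow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.ndimage import uniform_filter

from ischemap.errors import DimensionError, ValidationError

DEFAULT_WINDOW = 5  # pixels, spatial
DEFAULT_EPS = 1e-8


@dataclass
class SpeckleStack:
    """T raw speckle frames of nonnegative intensities (camera units)."""

    frames: np.ndarray          # (T, H, W)
    frame_rate: float = 30.0    # metadata only

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise DimensionError("SpeckleStack needs a (T, H, W) array, T >= 1")
        if np.any(self.frames < 0):
            raise ValidationError("speckle intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class ContrastImage:
    """Per-pixel speckle contrast K with the window that produced it."""

    values: np.ndarray                   # (H, W), K >= 0
    window: tuple = (DEFAULT_WINDOW, 1)  # (spatial_size, temporal_size)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValidationError("speckle contrast must be nonnegative")

    def save(self, path) -> None:
        tifffile.imwrite(path, self.values.astype(np.float32))

    @classmethod
    def load(cls, path, window=(DEFAULT_WINDOW, 1)) -> "ContrastImage":
        return cls(np.asarray(tifffile.imread(path), dtype=np.float64), window)


def compute_spatial_contrast(frame: np.ndarray, window_size: int = DEFAULT_WINDOW,
                             eps: float = DEFAULT_EPS) -> ContrastImage:
    """K = σ/⟨I⟩ over a sliding ``window_size``² neighbourhood of one frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise DimensionError("frame must be 2-D")
    if window_size % 2 == 0 or window_size < 3:
        raise ValidationError("window_size must be odd and >= 3")
    if min(frame.shape) < window_size:
        raise DimensionError(
            f"frame {frame.shape} smaller than window {window_size}")
    if np.any(frame < 0):
        raise ValidationError("negative intensities are not physical")
    # one-pass window variance on the globally centred frame: identical
    # estimator, but the cancellation error scales with local deviations
    # instead of absolute intensity (constant frames give exactly zero)
    center = frame.mean()
    d = frame - center
    mean_d = uniform_filter(d, size=window_size, mode="mirror")
    meansq_d = uniform_filter(d * d, size=window_size, mode="mirror")
    var = np.maximum(meansq_d - mean_d * mean_d, 0.0)
    mean = mean_d + center
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(var) / mean
    k[mean < eps] = 0.0
    return ContrastImage(k, window=(window_size, 1))


def compute_temporal_contrast(stack: SpeckleStack,
                              temporal_window: int,
                              eps: float = DEFAULT_EPS) -> ContrastImage:
    """Per-pixel K over sliding temporal windows, averaged across windows."""
    t = stack.n_frames
    if temporal_window < 2:
        raise ValidationError("temporal_window must be >= 2")
    if temporal_window > t:
        raise DimensionError(
            f"temporal_window {temporal_window} exceeds stack length {t}")
    frames = stack.frames
    acc = np.zeros(stack.shape)
    n_win = t - temporal_window + 1
    for start in range(n_win):
        win = frames[start:start + temporal_window]
        mean = win.mean(axis=0)
        sd = win.std(axis=0)  # population (ddof=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = sd / mean
        k[mean < eps] = 0.0
        acc += k
    return ContrastImage(acc / n_win, window=(1, temporal_window))


def contrast_to_flow(k: ContrastImage | np.ndarray,
                     eps: float = DEFAULT_EPS) -> np.ndarray:
    """Relative (unitless) flow index 1/max(K², eps).

    The proportionality constant linking 1/K² to absolute velocity depends
    on exposure and optics and is not recoverable, so the index is relative.
    """
    values = k.values if isinstance(k, ContrastImage) else np.asarray(k)
    if np.any(values < 0):
        raise ValidationError("speckle contrast must be nonnegative")
    if eps <= 0:
        raise ValidationError("eps must be positive")
    return 1.0 / np.maximum(values * values, eps)


def load_speckle_stack(path, frame_rate: float = 30.0) -> SpeckleStack:
    """Read a stack from a multi-page TIFF or a directory of PNG/TIFF frames."""
    import os

    import imageio.v3 as iio

    if os.path.isdir(path):
        names = sorted(
            f for f in os.listdir(path)
            if f.lower().endswith((".png", ".tif", ".tiff")))
        if not names:
            raise ValidationError(f"no frames found in {path}")
        frames = np.stack([
            np.asarray(iio.imread(os.path.join(path, f)), dtype=np.float64)
            for f in names])
    else:
        frames = np.asarray(tifffile.imread(path), dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[None]
    return SpeckleStack(frames, frame_rate=frame_rate)
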