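"""Preprocessing and training-time augmentation for cine windows.

Pipeline: CLAHE on each frame (local contrast enhancement against intensity
inhomogeneity), subject-level z-score normalization, then 5-frame temporal
windows with cyclic wrap-around (the cardiac cycle is periodic, so frame -1
is frame 19).  Augmentation applies one shared spatial transform — rotation
in [-90, 90] degrees, horizontal / vertical flips with probability 0.5 each,
and a smooth elastic deformation — to all five frames and masks of a window
(nearest-neighbor warping for masks), plus an image-only gamma shift drawn
from [0.5, 1.5].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import exposure

from .geometry import IndexVector

__all__ = ["InputWindow", "AugmentConfig", "zscore", "clahe", "augment",
           "temporal_window", "preprocess_subject_images"]

WINDOW = 5  # frames per input window; the target belongs to the center frame


@dataclass
class InputWindow:
    """A 5-frame input block with (optionally) masks and the center target."""

    frames: np.ndarray                 # (5, H, W) normalized intensities
    center_frame_index: int
    masks: np.ndarray | None = None    # (5, H, W) class field, training only
    target: IndexVector | None = None  # indices + phase of the center frame

    def __post_init__(self):
        if self.frames.shape[0] != WINDOW:
            raise ValueError(f"a window holds exactly {WINDOW} frames")
        if self.masks is not None and self.masks.shape != self.frames.shape:
            raise ValueError("mask stack must match the frame stack")


@dataclass
class AugmentConfig:
    rotation_deg: float = 90.0      # rotation drawn from [-rot, +rot]
    flip_prob: float = 0.5
    elastic_alpha: float = 2.0      # displacement amplitude, pixels
    elastic_spacing: float = 16.0   # control-point spacing (smoothing), pixels
    gamma_range: tuple[float, float] = (0.5, 1.5)


def zscore(images: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-subject z-score over the whole stack, with a std floor."""
    x = np.asarray(images, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty image stack")
    sd = x.std()
    return ((x - x.mean()) / max(sd, eps)).astype(np.float32)


def clahe(image: np.ndarray, clip_limit: float = 0.02,
          tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one frame.

    The frame is rescaled to [0, 1], equalized over a `tiles` x `tiles` grid
    with the given (normalized) clip limit, and mapped back to the input's
    intensity range, so the output respects the input range convention.
    A constant frame is returned unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        return img.astype(np.float32)
    unit = (img - lo) / (hi - lo)
    ker = max(1, img.shape[0] // tiles), max(1, img.shape[1] // tiles)
    eq = exposure.equalize_adapthist(unit, kernel_size=ker, clip_limit=clip_limit)
    return (lo + eq * (hi - lo)).astype(np.float32)


def preprocess_subject_images(images: np.ndarray, apply_clahe: bool = True,
                              clip_limit: float = 0.02, tiles: int = 8) -> np.ndarray:
    """CLAHE per frame (train and eval alike) followed by subject z-score."""
    stack = np.asarray(images, dtype=np.float32)
    if apply_clahe:
        stack = np.stack([clahe(f, clip_limit, tiles) for f in stack])
    return zscore(stack)


def _spatial_maps(shape, rng: np.random.Generator, cfg: AugmentConfig):
    """Sample one rigid+elastic transform; return output->input coordinate maps."""
    h, w = shape
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    flip_h = rng.random() < cfg.flip_prob     # left-right
    flip_v = rng.random() < cfg.flip_prob     # up-down
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    r, c = rows - cr, cols - cc
    if flip_h:
        c = -c
    if flip_v:
        r = -r
    a = np.deg2rad(angle)
    rs = np.cos(a) * r - np.sin(a) * c
    cs = np.sin(a) * r + np.cos(a) * c
    if cfg.elastic_alpha > 0:
        sigma = cfg.elastic_spacing / 2.0
        for arr in (rs, cs):
            disp = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
            scale = disp.std()
            if scale > 0:
                arr += cfg.elastic_alpha * disp / scale
    return rs + cr, cs + cc


def augment(window: InputWindow, rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> InputWindow:
    """Augmented copy of a training window (masks required).

    The identical spatial transform warps all 5 frames (linear interpolation)
    and all 5 masks (nearest neighbor); the gamma shift touches images only
    and is applied on each frame rescaled to [0, 1], preserving its range.
    """
    if window.masks is None:
        raise ValueError("augmentation needs the training masks")
    cfg = cfg or AugmentConfig()
    rmap, cmap = _spatial_maps(window.frames.shape[1:], rng, cfg)
    coords = np.stack([rmap, cmap])
    frames = np.stack([
        ndimage.map_coordinates(f, coords, order=1, mode="nearest")
        for f in window.frames]).astype(np.float32)
    masks = np.stack([
        ndimage.map_coordinates(m, coords, order=0, mode="constant", cval=0)
        for m in window.masks])
    gamma = rng.uniform(*cfg.gamma_range)
    out = np.empty_like(frames)
    for i, f in enumerate(frames):
        lo, hi = f.min(), f.max()
        if hi - lo > 0:
            out[i] = lo + ((f - lo) / (hi - lo)) ** gamma * (hi - lo)
        else:
            out[i] = f
    return InputWindow(out, window.center_frame_index, masks, window.target)


def temporal_window(images: np.ndarray, t: int,
                    masks: np.ndarray | None = None,
                    indices: list | None = None) -> InputWindow:
    """The 5-frame cyclic window centered on frame t of one subject."""
    images = np.asarray(images)
    n = images.shape[0]
    if n < WINDOW:
        raise ValueError(f"subject has {n} frames; at least {WINDOW} required")
    if not 0 <= t < n:
        raise ValueError(f"frame {t} out of range [0, {n})")
    sel = [(t + d) % n for d in range(-2, 3)]
    return InputWindow(
        frames=images[sel],
        center_frame_index=t,
        masks=masks[sel] if masks is not None else None,
        target=indices[t] if indices is not None else None,
    )
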