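"""Hormone-positive pixel detection by thresholding.

Two staining modes are supported, matching how stained pancreatic sections
are usually imaged:

* **IHC** — color images of DAB (brown) chromogen on a hematoxylin
  counterstain. A pixel is positive iff its HSV triple falls inside a
  configured box; the hue interval may wrap through 0 deg so that red-browns
  on both sides of the hue origin form one interval.
* **IF** — grayscale immunofluorescence channels. A pixel is positive iff its
  normalized intensity is >= a threshold, either fixed or computed per image
  by Otsu's criterion.

Detection is pure thresholding — no blur, no morphology — except for an
optional minimum connected-component size filter, off by default.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import measure
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .config import DetectionConfig

__all__ = ["ModeMismatchError", "threshold_ihc", "threshold_if", "detect"]


class ModeMismatchError(ValueError):
    """Image dimensionality does not match the configured staining mode."""


def _apply_min_blob(mask: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1 or not mask.any():
        return mask
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts >= min_size
    return keep[labels]


def _normalize_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == bool:
        return img.astype(float)
    if np.issubdtype(img.dtype, np.integer):
        return img / float(np.iinfo(img.dtype).max)
    return np.clip(img.astype(float), 0.0, 1.0)


def threshold_ihc(image: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Boolean mask of pixels whose HSV triple lies in the configured box.

    ``image`` must be an RGB(A) array; hue bounds are in degrees and a
    wrapped interval (lower > upper) passes through 0 deg.
    """
    if config.mode != "ihc":
        raise ModeMismatchError(f"threshold_ihc called with mode={config.mode!r}")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] not in (3, 4):
        raise ModeMismatchError(
            f"ihc mode needs a 3-channel color image, got shape {img.shape}"
        )
    hsv = rgb2hsv(img[..., :3])
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]  # h, s, v all in [0, 1]
    h_lo = config.hsv_lower[0] / 360.0
    h_hi = config.hsv_upper[0] / 360.0
    if h_lo <= h_hi:
        hue_ok = (h >= h_lo) & (h <= h_hi)
    else:  # wrapped interval through 0 deg
        hue_ok = (h >= h_lo) | (h <= h_hi)
    mask = (
        hue_ok
        & (s >= config.hsv_lower[1])
        & (s <= config.hsv_upper[1])
        & (v >= config.hsv_lower[2])
        & (v <= config.hsv_upper[2])
    )
    return _apply_min_blob(mask, config.min_blob_size)


def threshold_if(image: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Boolean mask of grayscale pixels with intensity >= the threshold.

    Integer images are normalized by their dtype maximum. With
    ``if_threshold = "otsu"`` the threshold is computed per image; a constant
    image has no Otsu threshold, yields a warning and an all-negative mask.
    """
    if config.mode != "if":
        raise ModeMismatchError(f"threshold_if called with mode={config.mode!r}")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ModeMismatchError(
            f"if mode needs a single-channel image, got shape {img.shape}"
        )
    norm = _normalize_gray(img)
    if config.if_threshold == "otsu":
        if norm.min() == norm.max():
            warnings.warn(
                "constant image: Otsu threshold undefined, returning empty mask",
                UserWarning,
                stacklevel=2,
            )
            return np.zeros(norm.shape, dtype=bool)
        thr = float(threshold_otsu(norm))
    else:
        thr = float(config.if_threshold)
    mask = norm >= thr
    return _apply_min_blob(mask, config.min_blob_size)


def detect(image: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Dispatch to :func:`threshold_ihc` or :func:`threshold_if` by config mode."""
    if config.mode == "ihc":
        return threshold_ihc(image, config)
    return threshold_if(image, config)
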