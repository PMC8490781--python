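"""Subtraction image, contrast enhancement, and the red/green interval-
change overlay.

Sign convention: difference = warped current - original, so growth
(new or progressive enhancement) is positive and is rendered green;
regression (signal present at baseline only) is negative and rendered
red.  Everything else shows as enhanced grayscale with zero difference
at mid-gray 128.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _sk_label

from .grid import ImageGrid

log = logging.getLogger(__name__)

__all__ = ["SubtractionResult", "subtract", "enhance", "colour_code", "robust_noise_sigma"]


@dataclass
class SubtractionResult:
    difference: np.ndarray  # signed, intensity units
    enhanced: np.ndarray  # display raster in [0, 255], 0 -> 128
    overlay: np.ndarray  # (H, W, 3) uint8
    positive_mask: np.ndarray
    negative_mask: np.ndarray
    change_threshold: float


def subtract(original: ImageGrid, warped_current: ImageGrid) -> np.ndarray:
    """Pixelwise warped current minus original (growth positive)."""
    if original.shape != warped_current.shape:
        raise ValueError(
            f"raster mismatch: {original.shape} vs {warped_current.shape}"
        )
    return warped_current.pixels - original.pixels


def enhance(
    difference: np.ndarray, method: str = "window", window: float | None = None
) -> np.ndarray:
    """Map a signed difference raster to a display raster in [0, 255].

    ``window``: linear map with zero difference at mid-gray 128 and the
    window half-width W (default the 99th percentile of |difference|) at
    the endpoints — [-W, 0] maps onto [0, 128] and [0, +W] onto
    [128, 255], so 0 -> 128 and +/-W -> {255, 0} exactly; values beyond
    the window clip.  ``clahe``: adaptive equalisation of the window
    output.
    """
    if method not in ("window", "clahe"):
        raise ValueError(f"unknown enhancement method {method!r}")
    diff = np.asarray(difference, dtype=float)
    w = float(np.percentile(np.abs(diff), 99)) if window is None else float(window)
    if w <= 0:
        return np.full(diff.shape, 128.0)
    out = np.where(diff >= 0, 128.0 + diff * (127.0 / w), 128.0 + diff * (128.0 / w))
    out = np.clip(out, 0.0, 255.0)
    if method == "clahe":
        from skimage.exposure import equalize_adapthist

        out = equalize_adapthist(out / 255.0) * 255.0
    return out


def robust_noise_sigma(difference: np.ndarray) -> float:
    """Noise scale of a difference raster from the median absolute
    deviation (1.4826 * MAD, the Gaussian-consistent estimate)."""
    diff = np.asarray(difference, dtype=float)
    return float(1.4826 * np.median(np.abs(diff - np.median(diff))))


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components with fewer than ``min_area`` pixels."""
    if min_area <= 1 or not mask.any():
        return mask
    lab = _sk_label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    return mask & (counts[lab] >= min_area)


def colour_code(
    difference: np.ndarray,
    change_threshold: float | None = None,
    min_area: int = 25,
    enhanced: np.ndarray | None = None,
) -> SubtractionResult:
    """Colour-coded progression overlay.

    Pixels with difference >= +threshold form the positive (growth) mask,
    rendered pure green; difference <= -threshold forms the negative
    (regression) mask, rendered pure red; everything else is the enhanced
    grayscale.  Components smaller than ``min_area`` pixels are removed
    from both masks.  The default threshold is 3x the robust noise sigma
    of the difference (floored at 0.5 intensity units so it stays
    positive on noiseless input).
    """
    diff = np.asarray(difference, dtype=float)
    if change_threshold is None:
        change_threshold = max(3.0 * robust_noise_sigma(diff), 0.5)
    if change_threshold <= 0:
        raise ValueError("change_threshold must be > 0")

    pos = _drop_small(diff >= change_threshold, min_area)
    neg = _drop_small(diff <= -change_threshold, min_area)

    enh = enhance(diff) if enhanced is None else np.asarray(enhanced, dtype=float)
    gray = np.clip(np.rint(enh), 0, 255).astype(np.uint8)
    overlay = np.stack([gray, gray, gray], axis=-1)
    overlay[pos] = (0, 255, 0)
    overlay[neg] = (255, 0, 0)
    return SubtractionResult(
        difference=diff,
        enhanced=enh,
        overlay=overlay,
        positive_mask=pos,
        negative_mask=neg,
        change_threshold=float(change_threshold),
    )
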