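"""Abnormality segmentation by iterated mean-of-class-means thresholding
(ISODATA-style) plus per-ROI shape features.

The threshold update is the classic two-class scheme: partition pixels at
the current threshold T, take the two class means h1 (below T) and h2 (at
or above T), set T1 = (h1 + h2) / 2 and repeat while |T - T1| >= deltaT.
Binarisation assigns pixels at exactly the final threshold TF to the
upper class (>=).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

from .grid import ImageGrid

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdState",
    "RoiFeature",
    "iterative_threshold",
    "binarize",
    "extract_rois",
    "segment_abnormality",
    "temporal_features",
]


@dataclass
class ThresholdState:
    """Converged state of the iterative threshold."""

    T: float  # threshold entering the final iteration
    T1: float  # last update (h1 + h2) / 2
    h1: float  # mean intensity of the class below T
    h2: float  # mean intensity of the class at/above T
    TF: float  # final converged threshold
    deltaT: float
    iterations: int


@dataclass
class RoiFeature:
    """Shape/intensity features of one 8-connected component."""

    label: int
    area_px: int
    centroid: tuple[float, float]  # (x, y) pixels
    bbox: tuple[int, int, int, int]  # (x, y, w, h)
    major_axis: float  # mm
    minor_axis: float  # mm
    feret_diameter: float  # mm, max caliper over boundary pixel centres
    mean_intensity: float | None = None


def iterative_threshold(
    img: ImageGrid | np.ndarray,
    mask: np.ndarray | None = None,
    deltaT: float = 0.5,
    T0: float | None = None,
    max_iter: int = 500,
) -> ThresholdState:
    """Iterate T <- (mean below T + mean at/above T) / 2 to convergence.

    ``mask`` restricts the pixel population (e.g. to the brain); ``T0``
    defaults to the mean intensity of that population.  Termination is
    guaranteed: the threshold sequence over a finite intensity multiset
    either converges or cycles, and a detected cycle stops with the cycle
    mean as TF.
    """
    pixels = img.pixels if isinstance(img, ImageGrid) else np.asarray(img, dtype=float)
    values = pixels[mask] if mask is not None else pixels.ravel()
    if values.size == 0:
        raise ValueError("empty pixel population under the mask")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("degenerate (constant) image: threshold undefined")
    if deltaT <= 0:
        raise ValueError("deltaT must be > 0")

    T = float(values.mean()) if T0 is None else float(T0)
    seen: dict[float, int] = {}
    h1 = h2 = T1 = T
    for it in range(1, max_iter + 1):
        lower = values[values < T]
        upper = values[values >= T]
        h1 = float(lower.mean()) if lower.size else vmin
        h2 = float(upper.mean()) if upper.size else vmax
        T1 = (h1 + h2) / 2.0
        if abs(T - T1) < deltaT:
            return ThresholdState(T, T1, h1, h2, TF=T1, deltaT=deltaT, iterations=it)
        if T1 in seen:  # cycle: stop at the cycle mean
            cycle = list(seen)[seen[T1]:]
            TF = float(np.mean(cycle))
            log.info("threshold cycle of length %d; using cycle mean %.4f",
                     len(cycle), TF)
            return ThresholdState(T, T1, h1, h2, TF=TF, deltaT=deltaT, iterations=it)
        seen[T1] = len(seen)
        T = T1
    return ThresholdState(T, T1, h1, h2, TF=T1, deltaT=deltaT, iterations=max_iter)


def binarize(img: ImageGrid | np.ndarray, TF: float) -> np.ndarray:
    """Binary mask: 1 exactly where intensity >= TF."""
    if not np.isfinite(TF):
        raise ValueError("threshold must be finite")
    pixels = img.pixels if isinstance(img, ImageGrid) else np.asarray(img)
    return pixels >= TF


def _feret_diameter_px(mask: np.ndarray) -> float:
    """Max pairwise distance between boundary pixel centres."""
    from scipy.ndimage import binary_erosion

    boundary = mask & ~binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear points
            pass
    return float(pdist(pts).max())


def extract_rois(
    mask: np.ndarray,
    spacing: float = 1.0,
    min_area: int = 25,
    intensity: np.ndarray | None = None,
) -> list[RoiFeature]:
    """8-connected components of a binary mask with area >= ``min_area``,
    sorted by area descending.

    Axis lengths come from the second-order moments (the ellipse with
    matching moments); the Feret diameter is the maximal caliper width
    over boundary pixel centres.  Lengths are in mm via ``spacing``.
    """
    mask = np.asarray(mask).astype(bool)
    labelled = _sk_label(mask, connectivity=2)
    feats: list[RoiFeature] = []
    for p in regionprops(labelled, intensity_image=intensity):
        if p.area < min_area:
            continue
        y0, x0, y1, x1 = p.bbox
        feats.append(
            RoiFeature(
                label=int(p.label),
                area_px=int(p.area),
                centroid=(float(p.centroid[1]), float(p.centroid[0])),
                bbox=(int(x0), int(y0), int(x1 - x0), int(y1 - y0)),
                major_axis=float(p.axis_major_length) * spacing,
                minor_axis=float(p.axis_minor_length) * spacing,
                feret_diameter=_feret_diameter_px(labelled == p.label) * spacing,
                mean_intensity=(float(p.intensity_mean) if intensity is not None else None),
            )
        )
    feats.sort(key=lambda f: (-f.area_px, f.label))
    return feats


def segment_abnormality(
    img: ImageGrid,
    deltaT: float = 0.5,
    T0: float | None = None,
    min_area: int = 25,
) -> tuple[ThresholdState, np.ndarray, list[RoiFeature]]:
    """Two-pass hierarchical segmentation of suspicious regions.

    Pass 1 thresholds the whole image, separating head from background
    (partial-volume edge pixels fall below this split).  Pass 2 reruns
    the iteration restricted to the extracted head, separating the
    hyperintense abnormality from normal parenchyma.  Returns the pass-2
    threshold state, the abnormality mask, and its ROI features.
    """
    pixels = img.pixels if isinstance(img, ImageGrid) else np.asarray(img, dtype=float)
    spacing = img.pixel_spacing if isinstance(img, ImageGrid) else 1.0
    head = binarize(pixels, iterative_threshold(pixels, deltaT=deltaT).TF)
    state = iterative_threshold(pixels, mask=head, deltaT=deltaT, T0=T0)
    mask = binarize(pixels, state.TF) & head
    rois = extract_rois(mask, spacing=spacing, min_area=min_area, intensity=pixels)
    return state, mask, rois


def temporal_features(roi_t1: RoiFeature, roi_t2: RoiFeature) -> dict[str, float]:
    """Five interval-change features: current-image ROI values minus the
    original-image ROI values (area, mean intensity, Feret diameter and
    the two centroid coordinates)."""
    d_mean = 0.0
    if roi_t1.mean_intensity is not None and roi_t2.mean_intensity is not None:
        d_mean = roi_t2.mean_intensity - roi_t1.mean_intensity
    return {
        "d_area_px": float(roi_t2.area_px - roi_t1.area_px),
        "d_mean_intensity": d_mean,
        "d_feret_mm": roi_t2.feret_diameter - roi_t1.feret_diameter,
        "d_centroid_x": roi_t2.centroid[0] - roi_t1.centroid[0],
        "d_centroid_y": roi_t2.centroid[1] - roi_t1.centroid[1],
    }
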