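"""Align the current (follow-up) image to the original.

Three stages, mirroring how temporal subtraction schemes register serial
radiographs:

1. **Global shift** — normalised cross-correlation (NCC) template
   matching of a central template from the original against a search
   window in the current image; integer offsets, optional parabolic
   sub-pixel refinement.
2. **Rotation search** — grid search over candidate angles minimising the
   sum of squared intensity differences after un-rotating the current
   image about a centre point.
3. **Twirl warp** — a non-linear polar warp: each output pixel at radius
   r < r_max from the warp centre samples the input at the same radius
   but at a polar angle advanced by alpha * (r_max - r) / r_max, i.e. the
   full rotation alpha at the centre decaying linearly to zero at r_max;
   pixels beyond r_max are copied unchanged.  r_max = inf is the
   rigid-rotation limit (decay factor 1 everywhere).

`register` chains the three: the shift estimate, then a residual-RMSE fit
of (alpha, r_max) over configured grids, always keeping the identity
transform as a candidate so registration can never increase the residual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import match_template

from .grid import ImageGrid

log = logging.getLogger(__name__)

__all__ = [
    "ShiftEstimate",
    "TwirlTransform",
    "RegistrationResult",
    "RegistrationConfig",
    "estimate_shift",
    "estimate_rotation",
    "twirl_warp",
    "register",
]


@dataclass(frozen=True)
class ShiftEstimate:
    """Integer (or sub-pixel refined) displacement of the current image
    content relative to the original: x positive rightward, y downward."""

    dtx: float
    dty: float
    peak_ncc: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.peak_ncc <= 1.0 + 1e-9:
            raise ValueError(f"peak_ncc must lie in [-1, 1], got {self.peak_ncc}")


@dataclass(frozen=True)
class TwirlTransform:
    """Decaying-rotation warp parameters plus the preceding global shift.

    ``alpha`` is the rotation (radians) applied at the warp centre,
    decaying linearly to zero at radius ``r_max`` (pixels; ``inf`` gives
    a rigid rotation).  ``shift`` is undone by a rigid translation before
    the warp is applied.
    """

    centre: tuple[float, float]  # (xC, yC)
    alpha: float  # radians
    r_max: float  # pixels, may be inf
    shift: ShiftEstimate = field(default_factory=lambda: ShiftEstimate(0.0, 0.0, 1.0))

    def __post_init__(self) -> None:
        if not self.r_max > 0:
            raise ValueError(f"r_max must be > 0, got {self.r_max}")


@dataclass
class RegistrationResult:
    transform: TwirlTransform
    warped_current: ImageGrid
    residual_rmse: float  # intensity RMSE over the brain mask


@dataclass
class RegistrationConfig:
    """Knobs for :func:`register`; defaults scale with the image size.

    ``template_roi`` is (x, y, w, h); ``None`` means the central block of
    half the image side.  Angle grids are degrees.  ``rmax_grid`` entries
    are pixels; ``inf`` adds the rigid-rotation candidate.
    """

    template_roi: tuple[int, int, int, int] | None = None
    search_radius: int = 15
    subpixel: bool = False
    alpha_grid_deg: tuple[float, ...] = tuple(np.arange(-10.0, 10.0 + 0.25, 0.5))
    rmax_grid: tuple[float, ...] | None = None  # default: size/4, 3size/8, size/2, inf
    brain_mask_fraction: float = 0.05  # mask = original > fraction * max
    min_improvement: float = 0.05  # relative residual gain a warp must deliver


def _central_roi(shape: tuple[int, int]) -> tuple[int, int, int, int]:
    rows, cols = shape
    w, h = cols // 2, rows // 2
    return ((cols - w) // 2, (rows - h) // 2, w, h)


def estimate_shift(
    original: ImageGrid,
    current: ImageGrid,
    template_roi: tuple[int, int, int, int] | None = None,
    search_radius: int = 15,
    subpixel: bool = False,
) -> ShiftEstimate:
    """Global shift of ``current`` relative to ``original`` by NCC
    template matching.

    A template cut from ``original`` at ``template_roi`` (x, y, w, h) is
    matched against the window of ``current`` obtained by dilating the
    ROI by ``search_radius`` pixels; the returned (dtx, dty) maximises
    the NCC.  Ties are broken toward the smallest |dtx| + |dty|, then
    lexicographically on (dtx, dty).
    """
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    roi = template_roi if template_roi is not None else _central_roi(original.shape)
    x, y, w, h = roi
    rows, cols = original.shape
    if x < 0 or y < 0 or x + w > cols or y + h > rows:
        raise ValueError(f"template ROI {roi} does not fit inside the original image")
    if (
        x - search_radius < 0
        or y - search_radius < 0
        or x + w + search_radius > current.shape[1]
        or y + h + search_radius > current.shape[0]
    ):
        raise ValueError(
            f"template ROI {roi} dilated by search_radius {search_radius} "
            "does not fit inside the current image"
        )

    template = original.pixels[y : y + h, x : x + w]
    if float(template.std()) == 0.0:
        raise ValueError(f"zero-variance template at ROI {roi}: NCC undefined")
    window = current.pixels[
        y - search_radius : y + h + search_radius,
        x - search_radius : x + w + search_radius,
    ]
    ncc = match_template(window, template)  # (2R+1, 2R+1)
    ncc = np.clip(ncc, -1.0, 1.0)

    best = float(ncc.max())
    iy, ix = np.nonzero(ncc >= best - 1e-12)
    cand = sorted(
        zip(ix - search_radius, iy - search_radius),
        key=lambda c: (abs(c[0]) + abs(c[1]), c[0], c[1]),
    )
    dtx, dty = int(cand[0][0]), int(cand[0][1])
    peak = float(ncc[dty + search_radius, dtx + search_radius])

    fx, fy = float(dtx), float(dty)
    if subpixel:
        fx += _parabolic_offset(ncc[dty + search_radius, :], dtx + search_radius)
        fy += _parabolic_offset(ncc[:, dtx + search_radius], dty + search_radius)
    return ShiftEstimate(fx, fy, peak)


def _parabolic_offset(line: np.ndarray, i: int) -> float:
    """Sub-pixel peak offset from a 3-point parabola; 0 at the border."""
    if i <= 0 or i >= len(line) - 1:
        return 0.0
    denom = line[i - 1] - 2 * line[i] + line[i + 1]
    if denom >= 0:  # not a local maximum
        return 0.0
    return float(0.5 * (line[i - 1] - line[i + 1]) / denom)


def _rotate_about(arr: np.ndarray, angle_deg: float, centre: tuple[float, float]) -> np.ndarray:
    """Rotate image content by ``angle_deg`` about ``centre`` (+x toward
    +y for positive angles on the y-down raster), bilinear."""
    if angle_deg == 0.0:
        return arr
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    rows, cols = arr.shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dx, dy = xx - centre[0], yy - centre[1]
    # inverse of forward R = [[c,-s],[s,c]]
    sx = centre[0] + c * dx + s * dy
    sy = centre[1] - s * dx + c * dy
    return ndi.map_coordinates(arr, [sy, sx], order=1, mode="constant", cval=0.0)


def estimate_rotation(
    original: ImageGrid,
    current: ImageGrid,
    centre: tuple[float, float] | None = None,
    angle_grid_deg: list[float] | tuple[float, ...] = tuple(np.arange(-10.0, 10.5, 0.5)),
    mask: np.ndarray | None = None,
) -> float:
    """Grid angle (degrees) minimising the sum of squared differences
    between ``original`` and ``current`` un-rotated by that angle about
    ``centre``.  Ties break toward the smallest |angle|."""
    grid = list(angle_grid_deg)
    if not grid:
        raise ValueError("angle grid must be non-empty")
    if sorted(grid) != grid:
        raise ValueError("angle grid must be sorted")
    c = centre if centre is not None else original.centre
    best_angle, best_ssd = None, np.inf
    for angle in sorted(grid, key=lambda a: (abs(a), a)):
        unrot = _rotate_about(current.pixels, -angle, c)
        diff = unrot - original.pixels
        if mask is not None:
            diff = diff[mask]
        ssd = float(np.sum(diff * diff))
        if ssd < best_ssd:
            best_angle, best_ssd = angle, ssd
    return float(best_angle)


def twirl_warp(img: ImageGrid, t: TwirlTransform) -> ImageGrid:
    """Apply the decaying-rotation warp via inverse mapping.

    The global shift in ``t`` is undone first by a rigid translation.
    Then every output pixel (x', y') with dx = x' - xC, dy = y' - yC and
    r = sqrt(dx^2 + dy^2) <= r_max samples the input at polar angle
    beta = atan2(dy, dx) + alpha * (r_max - r) / r_max, same radius,
    with bilinear interpolation (edge padding outside the raster);
    pixels with r > r_max are copied unchanged.
    """
    arr = img.pixels
    if t.shift.dtx != 0.0 or t.shift.dty != 0.0:
        arr = ndi.shift(arr, (-t.shift.dty, -t.shift.dtx), order=1, mode="nearest")
    if t.alpha == 0.0:
        return img.with_pixels(arr.copy() if arr is img.pixels else arr)

    rows, cols = arr.shape
    xc, yc = t.centre
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dx, dy = xx - xc, yy - yc
    r = np.hypot(dx, dy)
    if math.isinf(t.r_max):
        factor = 1.0
        inside = np.ones_like(r, dtype=bool)
    else:
        factor = (t.r_max - r) / t.r_max
        inside = r <= t.r_max
    beta = np.arctan2(dy, dx) + t.alpha * factor
    sx = np.where(inside, xc + r * np.cos(beta), xx)
    sy = np.where(inside, yc + r * np.sin(beta), yy)
    out = ndi.map_coordinates(arr, [sy, sx], order=1, mode="nearest")
    out[~inside] = arr[~inside]  # exact copy beyond r_max
    return img.with_pixels(out)


def _masked_rmse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    d = (a - b)[mask]
    return float(np.sqrt(np.mean(d * d))) if d.size else 0.0


def register(
    original: ImageGrid, current: ImageGrid, config: RegistrationConfig | None = None
) -> RegistrationResult:
    """Full registration: global shift, then (alpha, r_max) fitted on the
    configured grids to minimise residual intensity RMSE over the brain
    mask.  The identity transform is always a candidate, so the residual
    after registration never exceeds the unregistered residual."""
    if original.shape != current.shape:
        raise ValueError("original and current must share a raster")
    cfg = config or RegistrationConfig()
    size = original.shape[0]
    rmax_grid = cfg.rmax_grid if cfg.rmax_grid is not None else (
        size / 4.0, 3 * size / 8.0, size / 2.0, math.inf,
    )
    centre = original.centre
    brain_mask = original.pixels > cfg.brain_mask_fraction * float(original.pixels.max())

    # Shift and rotation estimates are coupled (a rotation biases the NCC
    # peak and vice versa).  Alternate the two, starting from zero shift:
    # estimate the rotation, then re-match the template against the
    # *forward-rotated* original so the residual template mismatch is a
    # pure translation, and repeat until the pair stabilises.  Every
    # visited (alpha, shift) pair stays in the candidate pool.
    shift0 = estimate_shift(
        original, current, cfg.template_roi, cfg.search_radius, cfg.subpixel
    )
    zero_shift = ShiftEstimate(0.0, 0.0, shift0.peak_ncc)
    visited: list[tuple[float, ShiftEstimate]] = [(0.0, shift0)]
    alpha_deg, shift = 0.0, zero_shift
    for _ in range(3):
        shifted = twirl_warp(current, TwirlTransform(centre, 0.0, math.inf, shift))
        new_alpha = estimate_rotation(
            original, shifted, centre, sorted(cfg.alpha_grid_deg), mask=brain_mask
        )
        ref = original
        if new_alpha != 0.0:
            ref = original.with_pixels(_rotate_about(original.pixels, new_alpha, centre))
        try:
            new_shift = estimate_shift(
                ref, current, cfg.template_roi, cfg.search_radius, cfg.subpixel
            )
        except ValueError:  # rotation pushed the template out of content
            new_shift = shift
        converged = new_alpha == alpha_deg and (new_shift.dtx, new_shift.dty) == (
            shift.dtx, shift.dty,
        )
        alpha_deg, shift = new_alpha, new_shift
        visited.append((alpha_deg, shift))
        if converged:
            break

    # candidate transforms, identity first so ties resolve to it
    candidates = [TwirlTransform(centre, 0.0, math.inf, zero_shift)]
    seen: set[tuple] = set()
    for a_deg, sh in visited:
        key = (a_deg, sh.dtx, sh.dty)
        if key in seen:
            continue
        seen.add(key)
        candidates.append(TwirlTransform(centre, 0.0, math.inf, sh))
        if a_deg != 0.0:
            candidates += [
                TwirlTransform(centre, math.radians(a_deg), rm, sh)
                for rm in rmax_grid
            ]

    # A candidate must beat the running best by a relative margin: tiny
    # gains from warping genuine lesion change must not masquerade as
    # motion, so near-ties resolve toward the simpler transform.
    best: tuple[float, TwirlTransform, ImageGrid] | None = None
    for t in candidates:
        warped = twirl_warp(current, t)
        res = _masked_rmse(original.pixels, warped.pixels, brain_mask)
        if best is None or res < best[0] * (1.0 - cfg.min_improvement):
            best = (res, t, warped)
    res, t, warped = best
    log.info(
        "registration: shift=(%.2f, %.2f) alpha=%.2f deg r_max=%s rmse=%.4f",
        t.shift.dtx, t.shift.dty, math.degrees(t.alpha), t.r_max, res,
    )
    return RegistrationResult(transform=t, warped_current=warped, residual_rmse=res)
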