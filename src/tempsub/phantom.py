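"""Paired synthetic brain-like phantoms with known ground truth.

Each phantom is an elliptical "brain" on a dark background carrying an
elliptical tumour mass.  A pair consists of a baseline image (t1) and a
follow-up image (t2) in which the tumour may have changed size, shape,
location or intensity, and on which one of four global misregistration
classes (brain expansion, lateral inclination, inclination, rotation), a
global pixel shift and additive Gaussian noise may have been applied.
The returned truth records exactly what was applied, so registration,
segmentation, subtraction and measurement are all testable without any
external data.

Intensity model: background (brain) 100, tumour 180, outside the head 0,
on an arbitrary 0-255 scale; edges are anti-aliased over ~1 pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .grid import ImageGrid
from .measurement import ellipsoid_volume

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "PhantomTruth",
    "MISREGISTRATION_CLASSES",
    "generate_pair",
    "apply_misregistration",
]

MISREGISTRATION_CLASSES = (
    "none",
    "brain_expansion",
    "lateral_inclination",
    "inclination",
    "rotation",
)


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in pixel coordinates: centre (x, y), half-axes (a, b)
    along the rotated axes, orientation in degrees (x-axis toward y-down),
    and a fill intensity."""

    centre: tuple[float, float]
    half_axes: tuple[float, float]
    orientation_deg: float = 0.0
    intensity: float = 180.0

    def normalised_radius(self, shape: tuple[int, int]) -> np.ndarray:
        """rho(x, y): 1 on the boundary, < 1 inside."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        dx, dy = xx - self.centre[0], yy - self.centre[1]
        th = np.deg2rad(self.orientation_deg)
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        a, b = self.half_axes
        return np.sqrt((u / a) ** 2 + (v / b) ** 2)

    def coverage(self, shape: tuple[int, int]) -> np.ndarray:
        """Approximate pixel coverage in [0, 1], anti-aliased over ~1 px."""
        rho = self.normalised_radius(shape)
        scale = min(self.half_axes)  # px per unit rho near the boundary
        return np.clip((1.0 - rho) * scale + 0.5, 0.0, 1.0)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return self.normalised_radius(shape) <= 1.0


@dataclass
class PhantomSpec:
    """Full description of a synthetic follow-up pair.

    ``misregistration`` magnitudes: fractional radius increase for
    brain_expansion, tangent of the inclination angle for the two shears,
    degrees for rotation.  ``global_shift`` is (dtx, dty) in pixels
    (x positive rightward, y positive downward) applied to the follow-up
    image content.  ``noise_sigma`` is the std of additive Gaussian noise
    on the 0-255 intensity scale, added independently to both images.
    """

    image_size: int = 512
    background: Ellipse = field(
        default_factory=lambda: Ellipse((255.5, 255.5), (200.0, 160.0), 0.0, 100.0)
    )
    tumour_t1: Ellipse = field(
        default_factory=lambda: Ellipse((320.0, 210.0), (28.0, 20.0), 20.0, 180.0)
    )
    tumour_t2: Ellipse | None = field(
        default_factory=lambda: Ellipse((320.0, 210.0), (38.0, 27.0), 20.0, 180.0)
    )
    misregistration: str = "none"
    magnitude: float = 0.0
    global_shift: tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0
    pixel_spacing: float = 0.45
    slice_thickness: float = 5.0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.misregistration not in MISREGISTRATION_CLASSES:
            raise ValueError(
                f"unknown misregistration class {self.misregistration!r}; "
                f"expected one of {MISREGISTRATION_CLASSES}"
            )
        for name, tum in (("tumour_t1", self.tumour_t1), ("tumour_t2", self.tumour_t2)):
            if tum is not None and not _ellipse_inside(tum, self.background):
                raise ValueError(f"{name} does not lie fully inside the background ellipse")


@dataclass
class PhantomTruth:
    """What was actually applied to produce the pair."""

    applied_shift: tuple[float, float]
    applied_rotation: float  # degrees; 0 unless class == rotation
    applied_class: str
    magnitude: float
    tumour_mask_t1: np.ndarray
    tumour_mask_t2: np.ndarray  # in the (misregistered) t2 frame
    true_volumes: tuple[float, float]  # cm^3, ellipsoid fit at t1 / t2


def _ellipse_inside(inner: Ellipse, outer: Ellipse, n: int = 256) -> bool:
    """Check every boundary point of ``inner`` lies inside ``outer``."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    a, b = inner.half_axes
    th = np.deg2rad(inner.orientation_deg)
    bx = inner.centre[0] + a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
    by = inner.centre[1] + a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
    tho = np.deg2rad(outer.orientation_deg)
    dx, dy = bx - outer.centre[0], by - outer.centre[1]
    u = dx * np.cos(tho) + dy * np.sin(tho)
    v = -dx * np.sin(tho) + dy * np.cos(tho)
    ao, bo = outer.half_axes
    return bool(np.all((u / ao) ** 2 + (v / bo) ** 2 <= 1.0))


def _affine_warp(arr: np.ndarray, inv2x2: np.ndarray, centre: tuple[float, float]) -> np.ndarray:
    """Warp by the affine whose *inverse* linear part about ``centre`` is
    ``inv2x2`` (in (x, y) order), bilinear, constant 0 outside."""
    rows, cols = arr.shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dx, dy = xx - centre[0], yy - centre[1]
    sx = centre[0] + inv2x2[0, 0] * dx + inv2x2[0, 1] * dy
    sy = centre[1] + inv2x2[1, 0] * dx + inv2x2[1, 1] * dy
    return ndi.map_coordinates(arr, [sy, sx], order=1, mode="constant", cval=0.0)


def _misregistration_inverse(cls: str, magnitude: float) -> np.ndarray:
    """Inverse linear part (about the image centre) of the forward map."""
    if cls == "brain_expansion":
        s = 1.0 + magnitude
        if s <= 0:
            raise ValueError("brain_expansion magnitude must exceed -1")
        return np.array([[1 / s, 0.0], [0.0, 1 / s]])
    if cls == "lateral_inclination":  # forward: x' = x + m*(y - yc)
        return np.array([[1.0, -magnitude], [0.0, 1.0]])
    if cls == "inclination":  # forward: y' = y + m*(x - xc)
        return np.array([[1.0, 0.0], [-magnitude, 1.0]])
    if cls == "rotation":  # forward rotates +x toward +y (y-down raster)
        th = np.deg2rad(magnitude)
        c, s = np.cos(th), np.sin(th)
        # forward R = [[c, -s], [s, c]]; inverse is its transpose
        return np.array([[c, s], [-s, c]])
    raise ValueError(f"unknown misregistration class {cls!r}")


def apply_misregistration(img: ImageGrid, cls: str, magnitude: float) -> ImageGrid:
    """Apply one of the four global misregistration classes about the
    image centre (``none`` or magnitude 0 is the identity)."""
    if cls == "none" or magnitude == 0.0:
        if cls not in MISREGISTRATION_CLASSES:
            raise ValueError(f"unknown misregistration class {cls!r}")
        return img.copy()
    inv = _misregistration_inverse(cls, magnitude)
    return img.with_pixels(_affine_warp(img.pixels, inv, img.centre))


def _render(spec: PhantomSpec, tumour: Ellipse | None) -> np.ndarray:
    shape = (spec.image_size, spec.image_size)
    img = spec.background.intensity * spec.background.coverage(shape)
    if tumour is not None:
        img += (tumour.intensity - spec.background.intensity) * tumour.coverage(shape)
    return img


def _fit_volume(mask: np.ndarray, pixel_spacing: float, slice_thickness: float) -> float:
    """Ellipsoid volume (cm^3) from the moment-fitted in-plane axes of a
    binary mask plus the slice thickness as the out-of-plane extent."""
    if not mask.any():
        return 0.0
    from skimage.measure import regionprops

    props = regionprops(mask.astype(np.uint8))[0]
    length_cm = props.axis_major_length * pixel_spacing / 10.0
    width_cm = props.axis_minor_length * pixel_spacing / 10.0
    height_cm = slice_thickness / 10.0
    return ellipsoid_volume(length_cm, width_cm, height_cm, convention="classic")


def _shift_image(arr: np.ndarray, dtx: float, dty: float) -> np.ndarray:
    if dtx == 0.0 and dty == 0.0:
        return arr
    return ndi.shift(arr, (dty, dtx), order=1, mode="constant", cval=0.0)


def generate_pair(spec: PhantomSpec) -> tuple[ImageGrid, ImageGrid, PhantomTruth]:
    """Generate the (t1, t2, truth) triple described by ``spec``.

    t2 is t1's anatomy with the tumour replaced per ``tumour_t2``, the
    misregistration applied about the image centre, then the global shift,
    then additive noise.  Identical specs (same seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_size, spec.image_size)

    t1 = _render(spec, spec.tumour_t1)
    mask_t1 = spec.tumour_t1.mask(shape)

    t2 = _render(spec, spec.tumour_t2)
    cov_t2 = spec.tumour_t2.coverage(shape) if spec.tumour_t2 is not None else np.zeros(shape)

    applied_rotation = spec.magnitude if spec.misregistration == "rotation" else 0.0
    if spec.misregistration != "none" and spec.magnitude != 0.0:
        inv = _misregistration_inverse(spec.misregistration, spec.magnitude)
        centre = ((spec.image_size - 1) / 2.0,) * 2
        t2 = _affine_warp(t2, inv, centre)
        cov_t2 = _affine_warp(cov_t2, inv, centre)
    dtx, dty = spec.global_shift
    t2 = _shift_image(t2, dtx, dty)
    cov_t2 = _shift_image(cov_t2, dtx, dty)
    mask_t2 = cov_t2 >= 0.5

    if spec.noise_sigma > 0:
        t1 = np.clip(t1 + rng.normal(0.0, spec.noise_sigma, shape), 0.0, 255.0)
        t2 = np.clip(t2 + rng.normal(0.0, spec.noise_sigma, shape), 0.0, 255.0)

    truth = PhantomTruth(
        applied_shift=(dtx, dty),
        applied_rotation=applied_rotation,
        applied_class=spec.misregistration,
        magnitude=spec.magnitude,
        tumour_mask_t1=mask_t1,
        tumour_mask_t2=mask_t2,
        true_volumes=(
            _fit_volume(mask_t1, spec.pixel_spacing, spec.slice_thickness),
            _fit_volume(mask_t2, spec.pixel_spacing, spec.slice_thickness),
        ),
    )
    grid = dict(pixel_spacing=spec.pixel_spacing, slice_thickness=spec.slice_thickness)
    return ImageGrid(t1, **grid), ImageGrid(t2, **grid), truth
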