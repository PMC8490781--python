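"""The 2-D grayscale raster all pipeline stages operate on."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageGrid"]


@dataclass
class ImageGrid:
    """A single-slice grayscale image with physical metadata.

    Pixels are stored row-major with row 0 at the top and 0-based indices;
    x increases rightward (columns), y downward (rows).  All physical
    measurements derive from ``pixel_spacing`` (mm per pixel, isotropic)
    and ``slice_thickness`` (mm, the out-of-plane extent of the slice).
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0
    slice_thickness: float = 5.0
    intensity_range: tuple[float, float] = field(default=(0.0, 255.0))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixel_spacing <= 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.slice_thickness <= 0:
            raise ValueError(
                f"slice_thickness must be > 0, got {self.slice_thickness}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (rows, cols)

    @property
    def centre(self) -> tuple[float, float]:
        """Geometric centre as (x, y) in pixel coordinates."""
        rows, cols = self.pixels.shape
        return ((cols - 1) / 2.0, (rows - 1) / 2.0)

    def with_pixels(self, pixels: np.ndarray) -> "ImageGrid":
        """A copy of this grid carrying new pixel data, same metadata."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))

    def copy(self) -> "ImageGrid":
        return self.with_pixels(self.pixels.copy())
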