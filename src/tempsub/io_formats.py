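"""Read/write the image formats the pipeline touches and normalise them
to the working raster.

Supported on disk: single-frame monochrome DICOM, NIfTI (first slice of a
volume), and 8/16-bit PNG/TIFF.  Everything is normalised to a square
working raster (512x512 by default, the conventional matrix size for this
kind of subtraction work) with intensities linearly rescaled to [0, 255].
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .grid import ImageGrid

log = logging.getLogger(__name__)

__all__ = ["read_image", "write_image", "normalize_to_working"]

_PNG_EXTS = {".png", ".tif", ".tiff"}
_NIFTI_EXTS = {".nii"}
_DICOM_EXTS = {".dcm", ".dicom"}


def _infer_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] in _PNG_EXTS:
        return "png"
    if (suffixes and suffixes[-1] in _NIFTI_EXTS) or suffixes[-2:] == [".nii", ".gz"]:
        return "nifti"
    if suffixes and suffixes[-1] in _DICOM_EXTS:
        return "dicom"
    raise ValueError(f"cannot infer image format from {path.name!r}")


def _collapse_channels(arr: np.ndarray, path: Path) -> np.ndarray:
    """Reduce an (H, W, C) array to grayscale, rejecting true colour."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        channels = [arr[..., c] for c in range(arr.shape[2])]
        if all(np.array_equal(channels[0], c) for c in channels[1:]):
            return channels[0]
        raise ValueError(
            f"{path}: colour image with non-identical channels is not grayscale"
        )
    raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")


def read_image(
    path: str | Path,
    format: str | None = None,
    pixel_spacing: float = 1.0,
    slice_thickness: float = 5.0,
) -> ImageGrid:
    """Read a grayscale image into an :class:`ImageGrid`.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``{"dicom", "nifti", "png"}``; inferred from the extension
        when omitted (``png`` also covers TIFF).
    pixel_spacing, slice_thickness
        Defaults (mm) for formats that carry no geometry (PNG/TIFF).
        DICOM headers and NIfTI affines override them when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt == "png":
        import imageio.v3 as iio

        arr = _collapse_channels(np.asarray(iio.imread(path)), path)
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        rng = (float(info.min), float(info.max)) if info else (0.0, 255.0)
        return ImageGrid(arr.astype(np.float64), pixel_spacing, slice_thickness, rng)

    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = _collapse_channels(np.asarray(ds.pixel_array), path)
        spacing = pixel_spacing
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        thickness = float(getattr(ds, "SliceThickness", slice_thickness) or slice_thickness)
        arr = arr.astype(np.float64)
        return ImageGrid(arr, spacing, thickness, (float(arr.min()), float(arr.max())))

    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if data.ndim > 2:
            log.info("%s: taking first slice of a %s-D NIfTI volume", path, data.ndim)
            data = data[..., 0] if data.ndim == 3 else data.reshape(data.shape[:2] + (-1,))[..., 0]
        zooms = img.header.get_zooms()
        spacing = float(zooms[0]) if len(zooms) >= 1 and zooms[0] > 0 else pixel_spacing
        thickness = float(zooms[2]) if len(zooms) >= 3 and zooms[2] > 0 else slice_thickness
        # NIfTI stores x fastest; transpose to row-major (row 0 = top)
        return ImageGrid(data.T, spacing, thickness, (float(data.min()), float(data.max())))

    raise ValueError(f"unknown format {fmt!r}")


def write_image(img: ImageGrid, path: str | Path) -> Path:
    """Write an :class:`ImageGrid` as 8-bit PNG/TIFF or float NIfTI.

    PNG output clips to [0, 255] and rounds to uint8; NIfTI keeps float64
    and records the pixel spacing / slice thickness in the header zooms.
    """
    path = Path(path)
    fmt = _infer_format(path)
    if fmt == "png":
        import imageio.v3 as iio

        iio.imwrite(path, np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8))
    elif fmt == "nifti":
        import nibabel as nib

        # store as a single-slice 3-D volume so the thickness zoom survives
        nii = nib.Nifti1Image(img.pixels.T[:, :, np.newaxis], affine=np.diag(
            [img.pixel_spacing, img.pixel_spacing, img.slice_thickness, 1.0]))
        nii.header.set_zooms((img.pixel_spacing, img.pixel_spacing, img.slice_thickness))
        nib.save(nii, str(path))
    else:
        raise ValueError(f"write_image supports png/tiff and nifti, not {fmt!r}")
    return path


def normalize_to_working(img: ImageGrid, size: int = 512) -> ImageGrid:
    """Resample to a ``size``x``size`` raster and rescale intensity to [0, 255].

    Bilinear resampling; ``pixel_spacing`` is rescaled so the physical
    extent (pixels x spacing) of the slice is preserved.  A degenerate
    intensity range (constant image) maps to all-zeros with a warning.
    """
    if size < 64:
        raise ValueError(f"working size must be >= 64, got {size}")
    rows, cols = img.shape
    pix = img.pixels
    if (rows, cols) != (size, size):
        pix = _sk_resize(pix, (size, size), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    # conserve physical extent along the larger dimension
    spacing = img.pixel_spacing * max(rows, cols) / size

    lo, hi = float(pix.min()), float(pix.max())
    if hi == lo:
        log.warning("degenerate intensity range (constant image); mapping to zeros")
        pix = np.zeros_like(pix)
    else:
        pix = (pix - lo) * (255.0 / (hi - lo))
    return ImageGrid(pix, spacing, img.slice_thickness, (0.0, 255.0))
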