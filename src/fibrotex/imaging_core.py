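"""Calibrated grayscale images, stacks, TIFF I/O, projection and thresholding.

This module is the preprocessing front end shared by every quantification
stage: it defines the calibrated raster types (:class:`ImageGrid`,
:class:`ImageStack`, :class:`BinaryMask`), reads and writes single- and
multi-page grayscale TIFFs, produces maximum-intensity projections, computes
automatic intensity thresholds, and applies masks to yield images with an
explicit validity raster.

Conventions
-----------
* Rasters are row-major, origin at the top-left, 0-based indices.
* Foreground after thresholding is *strictly above* the threshold; ties go
  to background.
* Pixel size is in micrometres per pixel edge; z-step in micrometres.
  Explicit calibration arguments override file metadata; if neither is
  available reading fails rather than assuming a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImagingError",
    "DegenerateHistogramError",
    "ImageGrid",
    "ImageStack",
    "BinaryMask",
    "MaskedImage",
    "read_stack",
    "write_stack",
    "write_mask",
    "read_mask",
    "max_projection",
    "auto_threshold",
    "apply_mask",
]


class ImagingError(ValueError):
    """Raised for invalid images, masks or unreadable files."""


class DegenerateHistogramError(ImagingError):
    """Raised when automatic thresholding is attempted on a constant image."""


_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass(frozen=True)
class ImageGrid:
    """A single calibrated 2-D grayscale raster.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer intensities.
    bit_depth
        8 or 16; all intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size_um
        Physical edge length of one pixel, in micrometres.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.bit_depth not in _DTYPES:
            raise ImagingError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ImagingError(f"pixels must be a 2-D raster, got shape {px.shape}")
        if px.dtype.kind not in "ui":
            raise ImagingError(f"pixels must be integer-valued, got dtype {px.dtype}")
        if px.size and (int(px.min()) < 0 or int(px.max()) > self.max_intensity):
            raise ImagingError(
                f"intensities outside [0, {self.max_intensity}] for bit depth {self.bit_depth}"
            )
        if not (self.pixel_size_um > 0):
            raise ImagingError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px.astype(_DTYPES[self.bit_depth], copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class ImageStack:
    """An ordered z-stack of dimensionally identical :class:`ImageGrid` planes."""

    planes: tuple[ImageGrid, ...]
    z_step_um: float

    def __post_init__(self) -> None:
        planes = tuple(self.planes)
        if len(planes) < 1:
            raise ImagingError("a stack needs at least one plane")
        first = planes[0]
        for p in planes[1:]:
            if p.shape != first.shape or p.bit_depth != first.bit_depth:
                raise ImagingError("all planes must share shape and bit depth")
            if p.pixel_size_um != first.pixel_size_um:
                raise ImagingError("all planes must share pixel_size_um")
        if not (self.z_step_um > 0):
            raise ImagingError(f"z_step_um must be positive, got {self.z_step_um}")
        object.__setattr__(self, "planes", planes)

    def __len__(self) -> int:
        return len(self.planes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    @property
    def bit_depth(self) -> int:
        return self.planes[0].bit_depth

    @property
    def pixel_size_um(self) -> float:
        return self.planes[0].pixel_size_um

    def as_array(self) -> np.ndarray:
        """Planes stacked into a (z, rows, cols) array."""
        return np.stack([p.pixels for p in self.planes])


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground mask plus the thresholding provenance that made it."""

    pixels: np.ndarray
    source_method: str
    threshold_value: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImagingError(f"mask must be 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def area_fraction(self) -> float:
        return float(self.pixels.mean()) if self.pixels.size else 0.0


@dataclass(frozen=True)
class MaskedImage:
    """An image together with a per-pixel validity raster.

    Invalid pixels keep their stored intensity but are excluded from all
    downstream accumulation; in particular, co-occurrence counting skips any
    pixel pair in which either endpoint is invalid.
    """

    image: ImageGrid
    valid: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.valid)
        if v.shape != self.image.shape:
            raise ImagingError(
                f"validity raster shape {v.shape} != image shape {self.image.shape}"
            )
        object.__setattr__(self, "valid", v.astype(bool, copy=False))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _calibration_from_file(tf: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Extract (pixel_size_um, z_step_um) from ImageJ-style TIFF metadata."""
    pixel_size = None
    z_step = None
    meta = tf.imagej_metadata or {}
    unit = str(meta.get("unit", "")).lower()
    if unit in {"um", "micron", "microns", "µm", "μm"}:
        page = tf.pages[0]
        tag = page.tags.get("XResolution")
        if tag is not None:
            num, den = tag.value
            if num:
                pixel_size = den / num
        if "spacing" in meta:
            z_step = float(meta["spacing"])
    return pixel_size, z_step


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Planes are returned in file page order.  Explicit ``pixel_size_um`` /
    ``z_step_um`` arguments take precedence over file metadata; missing
    calibration with no override raises.  For a single-plane file the z-step
    is irrelevant and defaults to 1 µm when unspecified.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise ImagingError(f"unreadable file {path}: {exc}") from exc
    with tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise ImagingError("unsupported pixel type: expected single-sample grayscale")
        arr = tf.series[0].asarray()
        file_px, file_z = _calibration_from_file(tf)
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ImagingError(f"unsupported pixel type: dtype {arr.dtype} (need uint8/uint16)")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ImagingError(f"expected a 2-D image or 3-D stack, got shape {arr.shape}")

    px = pixel_size_um if pixel_size_um is not None else file_px
    if px is None:
        raise ImagingError(
            f"{path}: no pixel-size calibration in file and none supplied"
        )
    z = z_step_um if z_step_um is not None else file_z
    if z is None:
        if arr.shape[0] > 1:
            raise ImagingError(f"{path}: no z-step calibration in file and none supplied")
        z = 1.0
    planes = tuple(ImageGrid(plane, bit_depth, px) for plane in arr)
    return ImageStack(planes, z)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as an ImageJ-compatible grayscale TIFF with calibration."""
    data = stack.as_array()
    res = 1.0 / stack.pixel_size_um
    tifffile.imwrite(
        Path(path),
        data,
        imagej=True,
        resolution=(res, res),
        metadata={"spacing": stack.z_step_um, "unit": "um", "axes": "ZYX"},
    )


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Persist a mask as an 8-bit TIFF with foreground 255 and background 0."""
    tifffile.imwrite(Path(path), np.where(mask.pixels, 255, 0).astype(np.uint8))


def read_mask(path: str | Path, source_method: str = "file", threshold_value: float = 0.0) -> BinaryMask:
    """Load a mask written by :func:`write_mask` (any non-zero pixel is foreground)."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ImagingError(f"mask file must hold a single 2-D page, got shape {arr.shape}")
    return BinaryMask(arr > 0, source_method, threshold_value)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def max_projection(stack: ImageStack) -> ImageGrid:
    """Per-pixel maximum across all planes; calibration is preserved."""
    proj = np.maximum.reduce([p.pixels for p in stack.planes])
    return ImageGrid(proj, stack.bit_depth, stack.pixel_size_um)


def _otsu_threshold(pixels: np.ndarray, n_gray: int) -> int:
    """Exhaustive Otsu cut: argmax of between-class variance over all integer
    cut points, foreground strictly above the cut; ties take the lowest cut."""
    counts = np.bincount(pixels.ravel(), minlength=n_gray).astype(np.float64)
    values = np.arange(n_gray, dtype=np.float64)
    total = counts.sum()
    grand = counts @ values
    w0 = np.cumsum(counts)[:-1]          # background weight for cut t = pixels <= t
    s0 = np.cumsum(counts * values)[:-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (grand - s0) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(bcv))


def auto_threshold(image: ImageGrid, method: str = "otsu") -> BinaryMask:
    """Automatically threshold an image into a foreground mask.

    ``method`` is ``"otsu"`` (maximal between-class variance, the default) or
    ``"isodata"``.  Foreground is strictly above the returned threshold.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (no non-trivial partition exists).
    """
    px = image.pixels
    if int(px.min()) == int(px.max()):
        raise DegenerateHistogramError("degenerate histogram: constant image")
    if method == "otsu":
        thr = _otsu_threshold(px, image.max_intensity + 1)
    elif method == "isodata":
        from skimage.filters import threshold_isodata

        thr = float(threshold_isodata(px))
    else:
        raise ImagingError(f"unknown threshold method {method!r}")
    return BinaryMask(px > thr, method, float(thr))


def apply_mask(image: ImageGrid, mask: BinaryMask) -> MaskedImage:
    """Mark background pixels invalid; intensities are left untouched."""
    if mask.shape != image.shape:
        raise ImagingError(f"mask shape {mask.shape} != image shape {image.shape}")
    return MaskedImage(image, mask.pixels)
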