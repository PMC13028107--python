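"""Raster image I/O and preprocessing for mammogram pipelines.

Reads single-channel PGM/PNG/TIFF mammograms into double precision,
normalizes intensities to a fixed range, extracts the breast silhouette
by thresholding away the dark background, and serializes binary masks
(8-bit PNG) and instance label maps (16-bit PNG) losslessly.

Conventions: row-major arrays, 0-based indices, pixel centers on the
integer grid. All internal computation is float64 regardless of the
input bit depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "IntensityImage",
    "FormatError",
    "DegenerateInputError",
    "read_image",
    "read_mask",
    "normalize_intensity",
    "extract_breast_region",
    "write_mask",
    "write_label_map",
    "read_label_map",
]

# 8-connectivity for foreground components throughout the package
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class FormatError(ValueError):
    """Raised for images that violate the single-channel contract."""


class DegenerateInputError(ValueError):
    """Raised for inputs on which an operation is mathematically undefined."""


@dataclass
class IntensityImage:
    """A 2-D grayscale image with its native value range.

    Parameters
    ----------
    pixels : ndarray
        Real-valued ``(rows, cols)`` grid, float64.
    value_range : tuple of float
        ``(min, max)`` of the pixel values in native units.
    spacing : float, optional
        Physical pixel size in micrometres, if known.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    spacing: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise FormatError(f"image too small: {self.pixels.shape} (need >= 8x8)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.value_range is None:
            self.value_range = (float(self.pixels.min()), float(self.pixels.max()))

    def __array__(self, dtype=None, copy=None):
        arr = self.pixels
        if dtype is not None:
            arr = arr.astype(dtype)
        return arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(img) -> np.ndarray:
    """Return the float64 pixel grid of an IntensityImage or array-like."""
    if isinstance(img, IntensityImage):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def read_image(path) -> IntensityImage:
    """Read a single-channel PGM (P2/P5), PNG, or TIFF image.

    Pixel values are returned as float64 preserving the stored bit depth;
    the native ``(min, max)`` is recorded in ``value_range``.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises several backend-specific types
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    if arr.ndim == 3:
        raise FormatError(
            f"expected a single-channel image, got {arr.shape[-1]} channels in {path!r}"
        )
    if arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path!r}")
    return IntensityImage(arr.astype(np.float64))


def read_mask(path) -> np.ndarray:
    """Read a binary mask; any strictly positive pixel maps to 1."""
    img = read_image(path)
    return (img.pixels > 0).astype(np.uint8)


def normalize_intensity(img, A: float) -> IntensityImage:
    """Affinely rescale intensities to span exactly [0, A].

    Computes ``A * (I - min(I)) / (max(I) - min(I))``. Idempotent once
    applied (a second pass is the identity up to round-off).

    Raises
    ------
    DegenerateInputError
        If the image is constant (zero dynamic range).
    """
    if A <= 0:
        raise ValueError(f"normalization range A must be positive, got {A}")
    pix = as_pixels(img)
    lo, hi = float(pix.min()), float(pix.max())
    if hi <= lo:
        raise DegenerateInputError("constant image: intensity normalization undefined")
    out = A * (pix - lo) / (hi - lo)
    return IntensityImage(out, value_range=(0.0, float(A)))


def extract_breast_region(img, roi_threshold: float = 5.0) -> np.ndarray:
    """Segment the breast silhouette from the dark background.

    Thresholds the (0-255 scale) image at ``roi_threshold``, breaks
    thin noise bridges with a single binary opening, keeps the largest
    8-connected component, and fills its holes. This removes film
    labels, stray noise chains, and artifacts disconnected from the
    breast. Returns a {0,1} uint8 mask.
    """
    pix = as_pixels(img)
    fg = pix > roi_threshold
    if not fg.any():
        raise DegenerateInputError("no breast region above threshold")
    opened = ndimage.binary_opening(fg, structure=EIGHT_CONNECTED)
    if opened.any():  # keep tiny-but-real foregrounds intact
        fg = opened
    labels, n = ndimage.label(fg, structure=EIGHT_CONNECTED)
    if n > 1:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(areas)) + 1
        fg = labels == keep
    fg = ndimage.binary_fill_holes(fg)
    return fg.astype(np.uint8)


def write_mask(path, mask) -> None:
    """Write a {0,1} mask as an 8-bit PNG with values {0, 255}."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    iio.imwrite(path, (m.astype(np.uint8) * 255), extension=".png")


def write_label_map(path, labels) -> None:
    """Write an instance label map as a 16-bit PNG, ids preserved exactly."""
    lab = np.asarray(labels)
    if lab.min() < 0:
        raise ValueError("label maps must be non-negative")
    if lab.max() > 65535:
        raise OverflowError(
            f"label id {int(lab.max())} exceeds the 16-bit PNG range (65535)"
        )
    iio.imwrite(path, lab.astype(np.uint16), extension=".png")


def read_label_map(path) -> np.ndarray:
    """Read a label map written by :func:`write_label_map`."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError("label maps must be single-channel")
    return arr.astype(np.int64)
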