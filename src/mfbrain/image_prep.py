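"""Loading, enhancement and binarization of 2D brain-section images.

The pipeline works on single 2D slices: a raster image is loaded to a
unit-scaled grayscale array, optionally contrast-stretched / equalized /
upsampled, then thresholded into a binary brain mask whose foreground pixel
count gives the apparent section area ``A``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import exposure, measure, transform
from skimage.filters import threshold_otsu

__all__ = [
    "GrayImage",
    "BinaryMask",
    "EmptyMaskError",
    "load_image",
    "enhance",
    "binarize",
    "apparent_area",
]

# Rec. 709 luminance weights for RGB collapse.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

_MIN_SIDE = 8


class EmptyMaskError(ValueError):
    """Raised when an operation requires foreground but the mask has none."""


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale slice with intensities scaled to [0, 1].

    ``pixel_spacing`` is the physical side length of one pixel (arbitrary
    length units, default 1.0); it propagates to masks and areas.
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D array, got shape {px.shape}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValueError(
                f"image must be at least {_MIN_SIDE}x{_MIN_SIDE}, got {px.shape}"
            )
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} foreground mask sharing its source image's pixel spacing."""

    pixels: np.ndarray
    pixel_spacing: float = 1.0
    threshold: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D array, got shape {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def is_empty(self) -> bool:
        return int(self.pixels.sum()) == 0

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    def require_nonempty(self) -> "BinaryMask":
        if self.is_empty:
            raise EmptyMaskError("mask has no foreground pixels")
        return self


def load_image(path: str | Path) -> GrayImage:
    """Read a PNG/JPEG/TIFF/BMP raster into a unit-scaled :class:`GrayImage`.

    Color images are collapsed to luminance (0.2126 R + 0.7152 G + 0.0722 B);
    intensities are then min-max scaled to [0, 1]. A constant image maps to
    all zeros (there is no contrast to preserve).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P", "CMYK", "YCbCr"):
                arr = np.asarray(im.convert("RGB"), dtype=float)
                gray = arr @ _LUMA
            else:
                gray = np.asarray(im.convert(im.mode), dtype=float)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError(f"{path}: not a non-empty 2D image")
    lo, hi = float(gray.min()), float(gray.max())
    if hi > lo:
        gray = (gray - lo) / (hi - lo)
    else:
        gray = np.zeros_like(gray)
    return GrayImage(gray)


def enhance(
    img: GrayImage,
    p_low: float = 1.0,
    p_high: float = 99.0,
    equalize: bool = False,
    upsample: int = 1,
) -> GrayImage:
    """Contrast-stretch, optionally equalize, and optionally upsample.

    Applied in order: (1) linear stretch of the [p_low, p_high] intensity
    percentiles onto [0, 1] (no-op when the percentile range is degenerate),
    (2) histogram equalization if requested, (3) integer bicubic upsampling,
    which divides ``pixel_spacing`` by the factor. Output is clipped to
    [0, 1].
    """
    if not (0 <= p_low < 100 and 0 < p_high <= 100 and p_low < p_high):
        raise ValueError(f"invalid percentile window [{p_low}, {p_high}]")
    if not (isinstance(upsample, (int, np.integer)) and upsample >= 1):
        raise ValueError(f"upsample factor must be a positive integer, got {upsample!r}")
    px = img.pixels
    lo, hi = np.percentile(px, [p_low, p_high])
    if hi > lo:
        px = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    if equalize:
        px = exposure.equalize_hist(px)
    spacing = img.pixel_spacing
    if upsample > 1:
        px = transform.resize(
            px,
            (px.shape[0] * upsample, px.shape[1] * upsample),
            order=3,
            mode="reflect",
            anti_aliasing=False,
        )
        px = np.clip(px, 0.0, 1.0)
        spacing = spacing / upsample
    return GrayImage(px, pixel_spacing=spacing)


def binarize(
    img: GrayImage,
    method: str = "otsu",
    threshold: float | None = None,
    keep_largest: bool = False,
) -> BinaryMask:
    """Threshold an image into a foreground mask.

    ``method`` is ``"otsu"`` (256-bin histogram threshold) or ``"fixed"``
    with an explicit ``threshold`` in [0, 1]. Foreground is strictly above
    the threshold, so ties go to background. An empty result is returned
    (with a warning) rather than raised; downstream operations that need
    foreground reject it explicitly.
    """
    if method == "otsu":
        t = float(threshold_otsu(img.pixels, nbins=256))
    elif method == "fixed":
        if threshold is None or not (0.0 <= threshold <= 1.0):
            raise ValueError("fixed method requires a threshold in [0, 1]")
        t = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    fg = img.pixels > t
    if keep_largest and fg.any():
        labels = measure.label(fg, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()
    if not fg.any():
        warnings.warn(
            f"binarize produced an empty mask (threshold {t:.4g})", stacklevel=2
        )
    return BinaryMask(fg.astype(np.uint8), pixel_spacing=img.pixel_spacing, threshold=t)


def apparent_area(mask: BinaryMask) -> float:
    """Apparent section area: foreground pixel count times spacing squared."""
    mask.require_nonempty()
    return mask.foreground_count * mask.pixel_spacing**2
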