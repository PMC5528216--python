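"""Calibrated raster images and binary adipocyte masks.

Intensity conventions
---------------------
Image files use the standard *light-is-high* convention (0 = black).  The
histology literature this package follows states intensities the other way
round: 0 is white and the maximum value (255 or 65,535) is black, so that a
high threshold selects the darkly stained intervacuolar matrix.  A
:class:`RasterImage` records which convention its pixel values are in, and
every thresholding operation resolves the convention explicitly.  Converting
between the two is the involution ``v -> max_intensity - v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage

from .errors import ValidationError

#: ITU-R BT.709 luminance weights used for RGB -> grayscale conversion.
LUMINANCE_WEIGHTS = (0.2125, 0.7154, 0.0721)

DARK_HIGH = "dark_high"
LIGHT_HIGH = "light_high"


@dataclass(frozen=True)
class RasterImage:
    """A calibrated 2-D grayscale intensity grid.

    Parameters
    ----------
    pixels
        2-D integer array of intensities in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16.
    um_per_px
        Linear calibration, micrometres per pixel (> 0).
    convention
        ``"light_high"`` (file standard, 0 = black) or ``"dark_high"``
        (0 = white, max = black).
    """

    pixels: np.ndarray
    bit_depth: int
    um_per_px: float
    convention: str = LIGHT_HIGH

    def __post_init__(self):
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.um_per_px <= 0:
            raise ValidationError("um_per_px must be positive")
        if self.convention not in (DARK_HIGH, LIGHT_HIGH):
            raise ValidationError(f"unknown intensity convention {self.convention!r}")
        if self.pixels.ndim != 2:
            raise ValidationError("RasterImage requires a 2-D grid")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.max_intensity
        ):
            raise ValidationError("intensities outside the bit-depth range")

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        return float(self.pixels.size) * self.um_per_px**2

    def as_dark_high(self) -> np.ndarray:
        """Pixel values on the dark-is-high scale (max = black)."""
        if self.convention == DARK_HIGH:
            return self.pixels
        return self.max_intensity - self.pixels

    def to_convention(self, convention: str) -> "RasterImage":
        if convention == self.convention:
            return self
        return replace(
            self,
            pixels=self.max_intensity - self.pixels,
            convention=convention,
        )


@dataclass
class BinaryMask:
    """Adipocyte / intervacuolar partition of one image.

    ``adipocyte`` is True where the pixel was classed as lipid-filled
    adipocyte area, False where it was classed as intervacuolar matrix.
    ``provenance`` records the threshold and convention that produced the
    mask so a report can always say how it was made.
    """

    adipocyte: np.ndarray
    um_per_px: float
    provenance: dict = field(default_factory=dict)

    @property
    def adipocyte_fraction(self) -> float:
        return float(self.adipocyte.mean())

    @property
    def area_um2(self) -> float:
        return float(self.adipocyte.size) * self.um_per_px**2


def rgb_to_gray(rgb: np.ndarray, max_intensity: int) -> np.ndarray:
    """Collapse an RGB array to grayscale with the recorded luminance weights."""
    w = np.asarray(LUMINANCE_WEIGHTS)
    gray = rgb[..., :3].astype(np.float64) @ w
    return np.clip(np.rint(gray), 0, max_intensity).astype(
        np.uint8 if max_intensity < 256 else np.uint16
    )


def read_image(
    path: str | Path,
    um_per_px: float,
    *,
    refuse_rgb: bool = False,
) -> RasterImage:
    """Read a TIFF/PNG/JPEG image as a calibrated grayscale RasterImage.

    RGB input is converted to grayscale with :data:`LUMINANCE_WEIGHTS` unless
    ``refuse_rgb`` is set, in which case colour files raise
    :class:`~adipo.errors.ValidationError`.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:
        if refuse_rgb:
            raise ValidationError(f"{path.name}: RGB input refused")
        max_i = 255 if arr.dtype == np.uint8 else 65535
        arr = rgb_to_gray(arr, max_i)
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return RasterImage(
        pixels=arr.astype(np.uint8 if bit_depth == 8 else np.uint16),
        bit_depth=bit_depth,
        um_per_px=um_per_px,
        convention=LIGHT_HIGH,
    )


def write_image(image: RasterImage, path: str | Path) -> None:
    """Write as 8/16-bit grayscale TIFF or PNG, in light-is-high file form."""
    path = Path(path)
    std = image.to_convention(LIGHT_HIGH)
    arr = std.pixels.astype(np.uint8 if image.bit_depth == 8 else np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        PILImage.fromarray(arr).save(path)


def write_label_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label grid as a 16-bit TIFF."""
    if labels.max(initial=0) > 65535:
        raise ValidationError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))
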