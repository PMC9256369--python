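"""Image containers, quantization conventions, and file I/O.

Every operator in this package works on 2-D floating-point intensity
fields in [0, 1] ("gray images"); colour inputs are carried as an
:class:`RgbImage` of three such planes.  8-bit storage uses round-half-up
quantization so that one convention holds across histogram-based
operators and file round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio

__all__ = [
    "RgbImage",
    "GrayImage",
    "BinaryMask",
    "validate_gray",
    "extract_green_channel",
    "quantize_levels",
    "quantize_roundtrip",
    "load_rgb_image",
    "load_gray_image",
    "load_mask",
    "save_gray_image",
    "save_mask",
]

#: A 2-D float array with values in [0, 1].
GrayImage = np.ndarray

#: A 2-D boolean array (True = vessel or inside-FOV, depending on role).
BinaryMask = np.ndarray


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a finite 2-D intensity field in [0, 1]."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return img


@dataclass(frozen=True)
class RgbImage:
    """Three co-registered intensity planes in [0, 1].

    Loaded 8-bit pixels are divided by 255; the planes share one shape.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self) -> None:
        r = validate_gray(self.red)
        g = validate_gray(self.green)
        b = validate_gray(self.blue)
        if not (r.shape == g.shape == b.shape):
            raise ValueError("red/green/blue planes must share one shape")
        object.__setattr__(self, "red", r)
        object.__setattr__(self, "green", g)
        object.__setattr__(self, "blue", b)

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RgbImage":
        """Build from an (H, W, 3) float array in [0, 1]."""
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) array, got {arr.shape}")
        return cls(arr[..., 0], arr[..., 1], arr[..., 2])

    def to_array(self) -> np.ndarray:
        """Stack the planes into an (H, W, 3) array."""
        return np.stack([self.red, self.green, self.blue], axis=-1)

    def intensity(self) -> GrayImage:
        """Mean of the three channels, the I plane of HSI."""
        return (self.red + self.green + self.blue) / 3.0


def extract_green_channel(img: RgbImage) -> GrayImage:
    """Return the green plane — the fundus channel with the best
    vessel/background contrast — as a gray image."""
    return img.green.copy()


def quantize_levels(img: GrayImage, n_levels: int = 256) -> np.ndarray:
    """Map intensities in [0, 1] to integer levels 0..n_levels-1.

    Uses round-half-up (0.5 -> 128 at 256 levels), the single
    quantization convention of the package.
    """
    img = validate_gray(img)
    levels = np.floor(img * (n_levels - 1) + 0.5).astype(np.int64)
    return np.clip(levels, 0, n_levels - 1)


def quantize_roundtrip(img: GrayImage) -> GrayImage:
    """Snap intensities to the nearest 8-bit level: v -> round(255 v)/255.

    Idempotent; values outside [0, 1] are rejected.
    """
    return quantize_levels(img) / 255.0


# ---------------------------------------------------------------------------
# File I/O.  PNG/TIFF/JPEG/GIF accepted on input; outputs are lossless PNG.
# ---------------------------------------------------------------------------

def _read_array(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    return np.asarray(arr)


def load_rgb_image(path: str | Path) -> RgbImage:
    """Load a colour image file as an :class:`RgbImage`."""
    arr = _read_array(path)
    if arr.ndim == 2:  # grayscale file: replicate into three planes
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    else:
        arr = arr.astype(float)
        if arr.max() > 1.0:
            arr = arr / arr.max()
    return RgbImage.from_array(np.clip(arr, 0.0, 1.0))


def load_gray_image(path: str | Path) -> GrayImage:
    """Load a file as a single gray plane (colour inputs use the green
    channel)."""
    arr = _read_array(path)
    if arr.ndim == 3:
        return extract_green_channel(load_rgb_image(path))
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def load_mask(path: str | Path) -> BinaryMask:
    """Read a mask image as binary: threshold at half of its maximum."""
    arr = _read_array(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = arr.astype(float)
    if arr.max() == 0:
        return np.zeros(arr.shape, dtype=bool)
    return arr >= 0.5 * arr.max()


def save_gray_image(path: str | Path, img: GrayImage) -> None:
    """Write a gray image as 8-bit lossless PNG."""
    levels = quantize_levels(img).astype(np.uint8)
    iio.imwrite(Path(path), levels, extension=".png")


def save_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a binary mask as 8-bit PNG (0/255)."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), arr, extension=".png")
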