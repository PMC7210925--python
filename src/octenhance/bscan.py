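"""The B-scan image container and PNG/TIFF I/O.

A B-scan is a single 2-D cross-sectional OCT slice. Every module in the
package exchanges images through one currency: a float64 grid of
intensities in [0, 1]. Files are read and written as 8- or 16-bit
grayscale PNG or TIFF, mapped linearly to [0, 1] by bit depth.
Quantization uses round-half-to-even (numpy's default rounding), so a
constant 0.5 image encodes to 128 at 8 bits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import tifffile
from PIL import Image

from .errors import InputError

MIN_DIM = 8


@dataclass
class BScan:
    """Single-channel 2-D intensity grid in [0, 1] with free-form metadata."""

    pixels: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.validate()

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def validate(self) -> None:
        if self.pixels.ndim != 2:
            raise InputError(f"B-scan must be 2-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < MIN_DIM or w < MIN_DIM:
            raise InputError(f"B-scan must be at least {MIN_DIM}x{MIN_DIM}, got {h}x{w}")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("B-scan contains non-finite pixels")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InputError(
                f"B-scan intensities must lie in [0, 1], got "
                f"[{self.pixels.min():.4g}, {self.pixels.max():.4g}]"
            )

    def with_pixels(self, pixels: np.ndarray, **meta: Any) -> "BScan":
        """A copy carrying new pixels; metadata is merged, not replaced."""
        return BScan(pixels=pixels, meta={**self.meta, **meta})


def read_bscan(path: str | os.PathLike) -> BScan:
    """Read an 8- or 16-bit grayscale PNG/TIFF and map it linearly to [0, 1]."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif ext == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise InputError(f"unsupported format {ext!r}: expected .png, .tif or .tiff")
    if arr.ndim != 2:
        raise InputError(f"expected single-channel grayscale image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise InputError(f"unsupported pixel type {arr.dtype}: expected uint8 or uint16")
    scale = float(2**depth - 1)
    return BScan(pixels=arr.astype(np.float64) / scale, meta={"bit_depth": depth, "path": path})


def write_bscan(img: BScan, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write a B-scan as grayscale PNG/TIFF at the requested bit depth.

    Encoding is deterministic; intensities are quantized with
    round-half-to-even.
    """
    img.validate()
    if bit_depth not in (8, 16):
        raise InputError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = os.fspath(path)
    scale = 2**bit_depth - 1
    quantized = np.round(img.pixels * scale)
    arr = quantized.astype(np.uint8 if bit_depth == 8 else np.uint16)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif ext == ".png":
        Image.fromarray(arr).save(path)
    else:
        raise InputError(f"unsupported format {ext!r}: expected .png, .tif or .tiff")
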