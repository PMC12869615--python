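"""Calibrated raster containers and TIFF I/O.

``Image2D`` wraps a single grayscale frame with its physical pixel size;
``ImageStack`` a z-stack of identically calibrated frames; ``MaskImage`` a
binary mask that remembers how it was made.  All pixel coordinates in this
package are (x, y) with x = column and y = row, matching the convention of
the exported CSV tables; array indexing remains [row, col].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

__all__ = [
    "Image2D",
    "ImageStack",
    "MaskImage",
    "read_tiff",
    "write_tiff",
]


@dataclass(frozen=True)
class Image2D:
    """A single calibrated grayscale frame.

    Parameters
    ----------
    pixels : (H, W) ndarray
        Nonnegative scalar grid.  dtype uint8/uint16/float.
    pixel_size : float
        Physical pixel size in micrometres per pixel (must be > 0).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"Image2D requires a 2-D array, got shape {px.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def bit_depth(self) -> str:
        dt = self.pixels.dtype
        if dt == np.uint8:
            return "8"
        if dt == np.uint16:
            return "16"
        return "float"

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Same calibration, new pixel data (filters use this)."""
        return replace(self, pixels=pixels)

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)


@dataclass(frozen=True)
class ImageStack:
    """A z-stack of identically shaped, identically calibrated frames."""

    slices: tuple[Image2D, ...]
    z_step: float | None = None

    def __post_init__(self) -> None:
        sl = tuple(self.slices)
        if len(sl) < 1:
            raise ValueError("ImageStack requires at least one slice")
        shape0 = sl[0].shape
        for s in sl:
            if s.shape != shape0:
                raise ValueError("all stack slices must share one shape")
            if s.pixel_size != sl[0].pixel_size:
                raise ValueError("all stack slices must share one pixel size")
        object.__setattr__(self, "slices", sl)

    @classmethod
    def from_array(
        cls, arr: np.ndarray, pixel_size: float = 1.0, z_step: float | None = None
    ) -> "ImageStack":
        arr = np.asarray(arr)
        if arr.ndim != 3:
            raise ValueError(f"expected (Z, H, W) array, got shape {arr.shape}")
        return cls(tuple(Image2D(a, pixel_size) for a in arr), z_step=z_step)

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[Image2D]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> Image2D:
        return self.slices[i]

    @property
    def shape(self) -> tuple[int, int, int]:
        h, w = self.slices[0].shape
        return (len(self.slices), h, w)

    @property
    def pixel_size(self) -> float:
        return self.slices[0].pixel_size

    def as_array(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.slices])


@dataclass(frozen=True)
class MaskImage:
    """Binary mask with provenance (method name + parameters)."""

    pixels: np.ndarray
    provenance: str = ""
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("mask values must be in {0, 1}")
            px = px.astype(bool)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def area(self) -> int:
        return int(self.pixels.sum())


def read_tiff(path: str | Path, pixel_size: float = 1.0) -> Image2D | ImageStack:
    """Read a single- or multi-page TIFF into an Image2D or ImageStack."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        return Image2D(arr, pixel_size)
    if arr.ndim == 3:
        return ImageStack.from_array(arr, pixel_size)
    raise ValueError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")


def write_tiff(path: str | Path, img: Image2D | ImageStack | MaskImage) -> None:
    """Write an image, stack, or mask as TIFF (masks saved as 8-bit 0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(img, MaskImage):
        tifffile.imwrite(str(path), img.pixels.astype(np.uint8) * 255)
    elif isinstance(img, ImageStack):
        tifffile.imwrite(str(path), img.as_array())
    else:
        tifffile.imwrite(str(path), np.asarray(img.pixels))
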