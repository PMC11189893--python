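"""Raster readers/writers for images, integer label maps and float maps.

PNG and TIFF only.  Label maps are single-channel integer rasters (0 =
background); writing uses 16-bit so up to 65535 region IDs round-trip
exactly.  Float maps (probability, distance) are written as 32-bit float
TIFF, which is lossless for float32 data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


class RasterError(ValueError):
    pass


@dataclass
class ImageRecord:
    """A named intensity image, grayscale (H, W) or RGB (H, W, 3)."""

    name: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or px.shape[0] < 1 or px.shape[1] < 1:
            raise RasterError(f"{self.name}: expected HxW or HxWx3 pixels")
        if px.ndim == 3 and px.shape[2] not in (3, 4):
            raise RasterError(f"{self.name}: expected 3 color channels")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise RasterError(f"{self.name}: intensities must be finite and >= 0")
        if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def read_raster(path: str | Path) -> ImageRecord:
    """Read a PNG/TIFF image as an :class:`ImageRecord`."""
    path = Path(path)
    if path.suffix.lower() not in IMAGE_SUFFIXES:
        raise RasterError(f"{path.name}: only PNG/TIFF supported")
    return ImageRecord(name=path.stem, pixels=iio.imread(path))


def read_label_raster(path: str | Path) -> np.ndarray:
    """Read a single-channel integer label map (region IDs, 0 = background)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        # A flat-color RGB/RGBA mask is tolerated; true color is ambiguous.
        if arr.shape[2] >= 3 and not (
            np.array_equal(arr[..., 0], arr[..., 1])
            and np.array_equal(arr[..., 0], arr[..., 2])
        ):
            raise RasterError(
                f"{Path(path).name}: RGB label raster is ambiguous; "
                "supply a single-channel integer map"
            )
        arr = arr[..., 0]
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise RasterError(f"{Path(path).name}: label raster must be integer")
        arr = np.round(arr).astype(np.int64)
    if arr.min() < 0:
        raise RasterError(f"{Path(path).name}: negative label IDs")
    return arr.astype(np.int32)


def write_label_raster(labels: np.ndarray, path: str | Path) -> None:
    """Write a label map as a 16-bit single-channel raster."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise RasterError("more than 65535 region IDs cannot round-trip in 16 bits")
    path = Path(path)
    out = labels.astype(np.uint16)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, out)
    else:
        tifffile.imwrite(path, out)


def write_float_raster(values: np.ndarray, path: str | Path) -> None:
    """Write a float map (probability/distance) losslessly as 32-bit TIFF."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise RasterError("float rasters must be written as TIFF")
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))


def read_float_raster(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.float32)


def read_aoi_raster(path: str | Path) -> np.ndarray:
    """Read a binary area-of-interest mask; nonzero means 'use this pixel'."""
    return read_label_raster(path) > 0
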