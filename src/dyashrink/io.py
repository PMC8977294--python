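"""Grayscale image I/O: PNG, TIFF (8/16-bit) and single-frame DICOM.

Images are read into float64 grids; the source integer range is recorded so
writes can clip and quantize back to the native format. DICOM reads apply
the rescale slope/intercept to recover stored intensities.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
import tifffile

from .errors import UnsupportedFormatError
from .grid import ImageGrid

_RANGES = {np.dtype(np.uint8): (0.0, 255.0), np.dtype(np.uint16): (0.0, 65535.0)}


def _to_grid(arr, path) -> ImageGrid:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: only single-channel grayscale images are supported "
            f"(got shape {arr.shape})"
        )
    source_range = _RANGES.get(arr.dtype, (float(np.min(arr)), float(max(np.max(arr), np.min(arr) + 1))))
    return ImageGrid(arr.astype(np.float64), source_range)


def read_image(path) -> ImageGrid:
    """Read a grayscale PNG/TIFF/DICOM file into an ImageGrid."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        if arr.ndim != 2:
            raise UnsupportedFormatError(f"{path}: only single-frame DICOM is supported")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        values = slope * arr + intercept
        stored = _RANGES.get(ds.pixel_array.dtype, (0.0, 65535.0))
        return ImageGrid(values, (slope * stored[0] + intercept, slope * stored[1] + intercept))
    if suffix in (".tif", ".tiff"):
        return _to_grid(tifffile.imread(path), path)
    if suffix == ".png":
        return _to_grid(iio.imread(path), path)
    raise UnsupportedFormatError(f"{path}: unsupported format {suffix!r} (PNG/TIFF/DICOM)")


def write_image(path, image: ImageGrid, source_range=None):
    """Write an ImageGrid as PNG or TIFF, clipping and quantizing to the
    source range (8-bit when the range high is <= 255, else 16-bit)."""
    path = Path(path)
    low, high = source_range if source_range is not None else image.source_range
    values = np.clip(image.values, low, high)
    if high <= 255.0 and low >= 0.0:
        quantized = np.round(values).astype(np.uint8)
    else:
        scaled = (values - low) / (high - low) * 65535.0 if (low, high) != (0.0, 65535.0) else values
        quantized = np.round(scaled).astype(np.uint16)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, quantized)
    elif suffix == ".png":
        iio.imwrite(path, quantized)
    else:
        raise UnsupportedFormatError(f"{path}: unsupported output format {suffix!r} (PNG/TIFF)")
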