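"""The universal 2-D image carrier.

All processing happens on real-valued (float64) pixel grids regardless of the
source bit depth; the original integer range is remembered so images can be
written back in their native format.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidImageError


class ImageGrid:
    """A 2-D grid of real-valued intensities.

    Parameters
    ----------
    values : ndarray of shape (height, width)
        Pixel intensities, stored as float64.
    source_range : (low, high) tuple
        The intensity range of the source format, used when quantizing on
        write. Defaults to (0, 255), the 8-bit convention.
    """

    def __init__(self, values, source_range=(0.0, 255.0)):
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim != 2:
            raise InvalidImageError(f"expected a 2-D grid, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InvalidImageError(f"degenerate dimensions {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise InvalidImageError("image contains NaN or Inf values")
        low, high = float(source_range[0]), float(source_range[1])
        if not high > low:
            raise InvalidImageError(f"source_range must satisfy high > low, got ({low}, {high})")
        self.values = arr
        self.source_range = (low, high)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        """A new grid with the same source range but different pixel values."""
        return ImageGrid(values, self.source_range)


def as_array(image) -> np.ndarray:
    """Accept either an ImageGrid or a bare 2-D array; return float64 values.

    Bare arrays are validated the same way (finite, 2-D).
    """
    if isinstance(image, ImageGrid):
        return image.values
    return ImageGrid(image).values
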