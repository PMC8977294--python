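"""Image fidelity metrics (MSE, SNR) and ROI time-density-curve extraction.

MSE and SNR are computed on the native intensity scale of the reference —
both are scale-dependent quantities, so no re-normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedSNRError
from .grid import as_array


@dataclass
class RoiMask:
    """A set of (row, col) pixel positions summarized together."""

    member_positions: np.ndarray  # shape (n, 2), int
    label: str = "roi"

    def __post_init__(self):
        pos = np.asarray(self.member_positions, dtype=np.intp)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] == 0:
            raise ValueError("member_positions must be a non-empty (n, 2) array")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("ROI positions must be unique")
        self.member_positions = pos

    @classmethod
    def from_mask(cls, mask, label: str = "roi") -> "RoiMask":
        """Build from a boolean/nonzero raster mask."""
        rows, cols = np.nonzero(np.asarray(mask))
        return cls(np.column_stack([rows, cols]), label)

    def check_bounds(self, shape):
        rows, cols = self.member_positions.T
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
            raise IndexError(f"ROI positions outside image of shape {shape}")


@dataclass
class TimeDensityCurve:
    """Mean ROI intensity as a function of acquisition time."""

    times: np.ndarray
    densities: np.ndarray
    roi_label: str = "roi"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=np.float64)
        d = np.asarray(self.densities, dtype=np.float64)
        if t.size != d.size or t.size < 1:
            raise ValueError("times and densities must have equal length >= 1")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t.min() < 0:
            raise ValueError("times must be nonnegative")
        self.times, self.densities = t, d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "density": self.densities, "roi_label": self.roi_label}
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def mse(reference, candidate) -> float:
    """Mean squared per-pixel difference: (1/(M N)) sum (f - f_hat)^2."""
    ref, cand = as_array(reference), as_array(candidate)
    if ref.shape != cand.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {cand.shape}")
    return float(np.mean((ref - cand) ** 2))


def snr(reference, candidate) -> float:
    """SNR in decibels: 10 log10(sum f^2 / sum (f - f_hat)^2).

    Raises UndefinedSNRError when either the signal energy or the error
    energy is zero (identical images have infinite SNR; the caller must
    handle that case explicitly rather than receive a sentinel).
    """
    ref, cand = as_array(reference), as_array(candidate)
    if ref.shape != cand.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {cand.shape}")
    signal = float(np.sum(ref**2))
    error = float(np.sum((ref - cand) ** 2))
    if signal == 0.0:
        raise UndefinedSNRError("zero signal energy")
    if error == 0.0:
        raise UndefinedSNRError("zero error energy (identical images)")
    return float(10.0 * np.log10(signal / error))


def extract_tdc(frames, times, roi: RoiMask) -> TimeDensityCurve:
    """Time-density curve: mean intensity over the ROI for each frame.

    ``frames`` is an ordered sequence of same-shape images; ``times`` the
    matching acquisition times in seconds (strictly increasing).
    """
    arrays = [as_array(f) for f in frames]
    times = np.asarray(times, dtype=np.float64)
    if len(arrays) != times.size:
        raise ValueError(f"{len(arrays)} frames but {times.size} times")
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError("all frames must share dimensions")
    roi.check_bounds(shape)
    rows, cols = roi.member_positions.T
    densities = np.array([a[rows, cols].mean() for a in arrays])
    return TimeDensityCurve(times, densities, roi.label)
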