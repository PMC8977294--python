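"""Undecimated (à trous) two-direction dyadic wavelet analysis and synthesis.

The decomposition is the translation-invariant dyadic wavelet transform used
for edge-preserving denoising of medical images: every scale keeps the full
image size, deeper scales use the same filters with ``2**(j-1) - 1`` zeros
inserted between taps ("à trous"), and each scale carries exactly two
directional detail planes — horizontal (d=1) and vertical (d=2) — rather than
the three subbands of the decimated separable transform.

One ladder step, acting on the running approximation ``S``:

    A      = h_j * S          (low-pass along rows)
    W_j^1  = g_j * S          (high-pass along rows: horizontal detail)
    W_j^2  = g_j * A          (high-pass along columns of A: vertical detail)
    S_j    = h_j * A          (low-pass along columns)

with ``g = delta - h`` the complementary high-pass of the chosen smoothing
filter. Because the high-pass is the complement of the low-pass, the ladder
telescopes: ``S_{j-1} = W_j^1 + W_j^2 + S_j``, so synthesis is plane-wise
summation (unit-impulse synthesis filters) and reconstruction is exact to
machine precision for any boundary rule.

Filters are applied as centered correlations; for the symmetric default
filters this coincides with convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    InvalidDecompositionError,
    InvalidFilterError,
    InvalidImageError,
    ScaleLimitError,
)
from .grid import ImageGrid, as_array

BOUNDARY_MODES = {"symmetric": "reflect", "periodic": "wrap"}


@dataclass(frozen=True)
class FilterPair:
    """Analysis/synthesis filter taps defining the dyadic wavelet.

    ``center`` is the index of the filter origin within ``lowpass`` (and
    ``highpass``, which shares the alignment). The high-pass taps must sum to
    zero so a constant image produces zero detail coefficients; the factory
    constructors build ``highpass = delta - lowpass``, which also makes the
    analysis/synthesis quadruple perfectly reconstructing with unit-impulse
    synthesis filters.
    """

    lowpass: np.ndarray
    highpass: np.ndarray
    synthesis_lowpass: np.ndarray
    synthesis_highpass: np.ndarray
    center: int
    name: str = "custom"

    def __post_init__(self):
        for attr in ("lowpass", "highpass", "synthesis_lowpass", "synthesis_highpass"):
            taps = np.asarray(getattr(self, attr), dtype=np.float64)
            if taps.size == 0:
                raise InvalidFilterError(f"{attr} taps are empty")
            object.__setattr__(self, attr, taps)
        if abs(self.highpass.sum()) > 1e-12:
            raise InvalidFilterError(
                f"highpass taps must sum to zero, got {self.highpass.sum():g}"
            )
        if not 0 <= self.center < self.lowpass.size:
            raise InvalidFilterError("filter center outside tap range")


def _complement(lowpass, center):
    g = -np.asarray(lowpass, dtype=np.float64)
    g[center] += 1.0
    return g


def bspline_filters() -> FilterPair:
    """Cubic-B-spline smoothing filter [1,4,6,4,1]/16 with complementary
    high-pass — the standard à trous kernel for medical-image denoising."""
    h = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    return FilterPair(h, _complement(h, 2), np.array([1.0]), np.array([1.0]), 2, "bspline")


def haar_filters() -> FilterPair:
    """Two-tap averaging filter with complementary high-pass (Haar-type)."""
    h = np.array([0.5, 0.5])
    return FilterPair(h, _complement(h, 1), np.array([1.0]), np.array([1.0]), 1, "haar")


_FACTORIES = {"bspline": bspline_filters, "haar": haar_filters}


def get_filter_pair(name: str) -> FilterPair:
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise InvalidFilterError(
            f"unknown wavelet {name!r}; available: {sorted(_FACTORIES)}"
        ) from None


@dataclass
class DyadicDecomposition:
    """Full-size detail planes per (scale, direction) plus the coarse residual.

    ``details[j-1][d-1]`` is the detail plane at scale ``j`` (1-based) in
    direction ``d`` (1 = horizontal, 2 = vertical); every plane and the
    approximation have the source dimensions.
    """

    details: list[tuple[np.ndarray, np.ndarray]]
    approximation: np.ndarray
    source_height: int = field(init=False)
    source_width: int = field(init=False)

    def __post_init__(self):
        shape = self.approximation.shape
        for planes in self.details:
            if len(planes) != 2:
                raise InvalidDecompositionError("each scale needs exactly 2 directions")
            for p in planes:
                if p.shape != shape:
                    raise InvalidDecompositionError(
                        f"plane shape {p.shape} != approximation shape {shape}"
                    )
        self.source_height, self.source_width = shape

    @property
    def scales(self) -> int:
        return len(self.details)

    def detail(self, scale: int, direction: int) -> np.ndarray:
        """Detail plane W_j^d with 1-based scale and direction indices."""
        return self.details[scale - 1][direction - 1]

    def map_planes(self, fn) -> "DyadicDecomposition":
        """Apply ``fn`` to every plane (details and approximation)."""
        return DyadicDecomposition(
            [(fn(w1), fn(w2)) for w1, w2 in self.details], fn(self.approximation)
        )


def upsample_filter(taps, level: int) -> np.ndarray:
    """Level-``level`` à trous filter: insert ``2**(level-1) - 1`` zeros
    between consecutive taps. Level 1 returns the base taps unchanged."""
    taps = np.asarray(taps, dtype=np.float64)
    if taps.size == 0:
        raise InvalidFilterError("cannot upsample an empty tap sequence")
    if level < 1:
        raise InvalidFilterError(f"level must be >= 1, got {level}")
    step = 2 ** (level - 1)
    if step == 1:
        return taps.copy()
    out = np.zeros((taps.size - 1) * step + 1)
    out[::step] = taps
    return out


def _correlate(arr, taps, center, axis, boundary):
    mode = BOUNDARY_MODES[boundary]
    origin = center - taps.size // 2
    return ndimage.correlate1d(arr, taps, axis=axis, mode=mode, origin=origin)


def _check_boundary(boundary):
    if boundary not in BOUNDARY_MODES:
        raise ValueError(f"boundary must be one of {sorted(BOUNDARY_MODES)}")


def dyadic_forward(
    image, filters: FilterPair | None = None, scales: int = 3, boundary: str = "symmetric"
) -> DyadicDecomposition:
    """Undecimated dyadic wavelet analysis.

    Parameters
    ----------
    image : ImageGrid or 2-D array
    filters : FilterPair, default cubic B-spline
    scales : int
        Number of dyadic scales J; the level-J filter support
        ``2**(J-1) * len(h)`` must fit within the smaller image dimension.
    boundary : {"symmetric", "periodic"}
        Symmetric (mirror) reflection avoids edge artifacts on anatomy;
        periodic makes the transform exactly shift-equivariant.
    """
    if filters is None:
        filters = bspline_filters()
    _check_boundary(boundary)
    arr = as_array(image)
    if scales < 1:
        raise ScaleLimitError(f"scales must be >= 1, got {scales}")
    support = 2 ** (scales - 1) * filters.lowpass.size
    if support > min(arr.shape):
        raise ScaleLimitError(
            f"J={scales} needs filter support {support} > min image dim {min(arr.shape)}"
        )

    details = []
    approx = arr
    for j in range(1, scales + 1):
        h_j = upsample_filter(filters.lowpass, j)
        g_j = upsample_filter(filters.highpass, j)
        c_j = filters.center * 2 ** (j - 1)
        w1 = _correlate(approx, g_j, c_j, 1, boundary)  # horizontal detail
        a_row = _correlate(approx, h_j, c_j, 1, boundary)
        w2 = _correlate(a_row, g_j, c_j, 0, boundary)  # vertical detail
        approx = _correlate(a_row, h_j, c_j, 0, boundary)
        details.append((w1, w2))
    return DyadicDecomposition(details, approx)


def dyadic_inverse(
    decomposition: DyadicDecomposition,
    filters: FilterPair | None = None,
    boundary: str = "symmetric",
) -> np.ndarray:
    """Synthesis: rebuild the image from a (possibly modified) decomposition.

    With the complementary filter pairs built by this module the synthesis
    filters are unit impulses and the ladder telescopes to plane summation,
    which reconstructs an untouched decomposition exactly.
    """
    if filters is None:
        filters = bspline_filters()
    _check_boundary(boundary)
    slp, shp = filters.synthesis_lowpass, filters.synthesis_highpass
    approx = decomposition.approximation
    for w1, w2 in reversed(decomposition.details):
        if w1.shape != approx.shape or w2.shape != approx.shape:
            raise InvalidDecompositionError("inconsistent plane sizes")
        approx = (
            _correlate(_correlate(approx, slp, slp.size // 2, 0, boundary), slp, slp.size // 2, 1, boundary)
            + _correlate(w1, shp, shp.size // 2, 1, boundary)
            + _correlate(w2, shp, shp.size // 2, 0, boundary)
        )
    return approx


def equivalent_detail_filters(filters: FilterPair, scale: int) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """1-D (row, column) equivalent filters of the two scale-``scale``
    detail channels — the cascades of zero-inserted low-pass filters
    terminated by the zero-inserted high-pass.

    Returns a mapping ``direction -> (row_filter, col_filter)``.
    """
    if scale < 1:
        raise InvalidFilterError(f"scale must be >= 1, got {scale}")
    casc_prev = np.array([1.0])  # h_1 * ... * h_{j-1}
    for j in range(1, scale):
        casc_prev = np.convolve(casc_prev, upsample_filter(filters.lowpass, j))
    g_j = upsample_filter(filters.highpass, scale)
    h_j = upsample_filter(filters.lowpass, scale)
    band = np.convolve(casc_prev, g_j)
    return {
        1: (band, casc_prev),
        2: (np.convolve(casc_prev, h_j), band),
    }
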