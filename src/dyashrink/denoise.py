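"""Adaptive dyadic-wavelet denoising with neighborhood-window shrinkage.

The denoiser (registered as ``iwt``) runs the undecimated dyadic transform,
estimates the image noise level robustly from the finest-scale detail
coefficients (MAD / 0.6745), propagates the noise variance to every scale
through the à trous filter cascade, forms a per-subband adaptive threshold,
and shrinks each detail coefficient using a three-branch rule driven by the
maximum absolute coefficient inside a small window around it — coefficients
that sit near a strong neighbor (an edge) are kept or only partially shrunk,
isolated small coefficients (noise) are zeroed. The coarse approximation is
never thresholded. Synthesis then yields the denoised image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .grid import ImageGrid, as_array
from .wavelet import (
    BOUNDARY_MODES,
    DyadicDecomposition,
    FilterPair,
    bspline_filters,
    dyadic_forward,
    dyadic_inverse,
    equivalent_detail_filters,
    get_filter_pair,
)

MAD_TO_SIGMA = 0.6745  # median(|N(0,1)|)

THRESHOLD_RULES = ("bayes", "noisy-variance", "variance-ratio")

_BETA_FLOOR = 1e-12  # variance floor for near-constant subbands


@dataclass
class NoiseModel:
    """Global noise level and per-scale propagated coefficient variances."""

    sigma: float
    sigma_sq_per_scale: list[float]

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")
        if any(v < 0 for v in self.sigma_sq_per_scale):
            raise InvalidParameterError("propagated variances must be >= 0")


@dataclass
class ThresholdSet:
    """Per-subband thresholds lambda[j][d] with the quantities they came from.

    Lists are indexed ``[scale-1][direction-1]``; ``subband_width`` is the
    coefficient count L_j of each (full-size) subband.
    """

    lambdas: list[list[float]]
    subband_width_per_scale: list[int]
    coeff_variance: list[list[float]]
    J: int


@dataclass
class ShrinkageParams:
    """Window geometry for the neighborhood maximum.

    ``window_size`` is the odd side length m >= 3 of the square window
    centered on the coefficient being shrunk.
    """

    window_size: int = 3
    boundary: str = "symmetric"

    def __post_init__(self):
        m = self.window_size
        if m < 3 or m % 2 == 0:
            raise InvalidParameterError(f"window_size must be odd and >= 3, got {m}")
        if self.boundary not in BOUNDARY_MODES:
            raise InvalidParameterError(f"unknown boundary {self.boundary!r}")


@dataclass
class DenoiseDiagnostics:
    """Everything the denoiser decided: noise model, thresholds, branch counts."""

    noise_model: NoiseModel
    thresholds: ThresholdSet
    # per subband [scale-1][direction-1]: (kept, shrunk, zeroed)
    branch_counts: list[list[tuple[int, int, int]]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sigma": self.noise_model.sigma,
            "sigma_sq_per_scale": list(self.noise_model.sigma_sq_per_scale),
            "lambda_per_subband": [list(row) for row in self.thresholds.lambdas],
            "subband_width_per_scale": list(self.thresholds.subband_width_per_scale),
            "coeff_variance_per_subband": [list(r) for r in self.thresholds.coeff_variance],
            "scales": self.thresholds.J,
            "branch_counts": [
                [{"kept": k, "shrunk": s, "zeroed": z} for (k, s, z) in row]
                for row in self.branch_counts
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def estimate_sigma(finest_details) -> float:
    """Robust MAD noise estimate from finest-scale wavelet coefficients:
    ``median(|w|) / 0.6745``.

    Accepts one plane or a sequence of planes (both directions pooled).
    Returns 0 for all-zero input, which makes downstream denoising a no-op.
    """
    if isinstance(finest_details, (list, tuple)):
        pooled = np.concatenate([np.ravel(np.asarray(p)) for p in finest_details])
    else:
        pooled = np.ravel(np.asarray(finest_details))
    if pooled.size == 0:
        raise InvalidParameterError("need at least one coefficient to estimate sigma")
    return float(np.median(np.abs(pooled)) / MAD_TO_SIGMA)


def estimate_image_sigma(decomposition: DyadicDecomposition, filters: FilterPair) -> float:
    """Image-domain noise sigma from the scale-1 detail planes.

    Each directional plane sees the noise through a different equivalent
    filter, so each is normalized by its filter gain (root tap energy)
    before pooling; the pooled sample is then unit-gain and the plain MAD
    estimator recovers the pixel-domain sigma.
    """
    eq = equivalent_detail_filters(filters, 1)
    planes = []
    for d in (1, 2):
        row_f, col_f = eq[d]
        gain = float(np.sqrt(np.sum(row_f**2) * np.sum(col_f**2)))
        planes.append(decomposition.detail(1, d) / gain)
    return estimate_sigma(planes)


def propagate_noise_variance(
    sigma: float, filters: FilterPair, scale: int, direction: int | None = None
) -> float:
    """Noise variance sigma_j^2 of scale-``scale`` detail coefficients for
    i.i.d. pixel noise of standard deviation ``sigma``.

    The variance is ``sigma**2`` times the tap energy of the 2-D equivalent
    detail filter (the à trous cascade of zero-inserted low-pass filters
    terminated by the zero-inserted high-pass, separable row x column).
    The two directional subbands have slightly different energies;
    ``direction=None`` (default) returns their mean, which equals the
    variance of the pooled scale-j coefficient sample.
    """
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    eq = equivalent_detail_filters(filters, scale)
    energies = {
        d: float(np.sum(row_f**2) * np.sum(col_f**2)) for d, (row_f, col_f) in eq.items()
    }
    if direction is None:
        energy = 0.5 * (energies[1] + energies[2])
    else:
        energy = energies[direction]
    return sigma**2 * energy


def compute_threshold(
    sigma_sq_j: float,
    L_j: int,
    J: int,
    beta_j: float,
    rule: str = "bayes",
) -> float:
    """Per-subband adaptive threshold lambda_j.

    ``beta_j`` is the sample variance of the (noisy) subband coefficients;
    ``L_j`` its coefficient count. Every rule scales a noise-to-signal ratio
    by a log-size term that decays with decomposition depth,
    ``sqrt(ln(L_j) / J)`` (natural log):

    - ``"bayes"`` (default):
      ``lambda_j = (sigma_j^2 / sigma_x) * sqrt(ln(L_j)/J)`` with
      ``sigma_x = sqrt(max(beta_j - sigma_j^2, eps))`` the estimated spread
      of the noise-free signal component (BayesShrink-style). A subband
      with no signal content gets an effectively infinite threshold and is
      zeroed; signal-rich subbands are barely touched.
    - ``"noisy-variance"``:
      ``lambda_j = (sigma_j^2 / sqrt(beta_j)) * sqrt(ln(L_j)/J)`` — same
      form but with the raw coefficient spread in the denominator; milder.
    - ``"variance-ratio"``:
      ``lambda_j = (sigma_j^2 / beta_j) * sqrt(ln(L_j)/J)``, the
      dimensionless variance-over-variance variant, kept for comparison
      (its thresholds are not in coefficient units and shrink very little).

    Returns 0 when the subband is noiseless (``sigma_sq_j == 0``) or trivial
    (``L_j == 1``).
    """
    if L_j < 1:
        raise InvalidParameterError(f"L_j must be >= 1, got {L_j}")
    if J < 1:
        raise InvalidParameterError(f"J must be >= 1, got {J}")
    if beta_j <= 0:
        raise InvalidParameterError(f"beta_j must be > 0, got {beta_j}")
    if rule not in THRESHOLD_RULES:
        raise InvalidParameterError(f"rule must be one of {THRESHOLD_RULES}, got {rule!r}")
    if sigma_sq_j < 0:
        raise InvalidParameterError(f"sigma_sq_j must be >= 0, got {sigma_sq_j}")
    if sigma_sq_j == 0 or L_j == 1:
        return 0.0
    depth_term = np.sqrt(np.log(L_j) / J)
    if rule == "bayes":
        sigma_x = np.sqrt(max(beta_j - sigma_sq_j, _BETA_FLOOR))
        return float(sigma_sq_j / sigma_x * depth_term)
    if rule == "noisy-variance":
        return float(sigma_sq_j / np.sqrt(beta_j) * depth_term)
    return float(sigma_sq_j / beta_j * depth_term)


def window_max(plane, row: int, col: int, params: ShrinkageParams | None = None) -> float:
    """Maximum absolute coefficient in the m x m window centered at
    (row, col); out-of-bounds positions follow the boundary rule."""
    if params is None:
        params = ShrinkageParams()
    plane = np.asarray(plane)
    n_rows, n_cols = plane.shape
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise IndexError(f"position ({row}, {col}) outside plane {plane.shape}")
    half = params.window_size // 2
    pad_mode = "symmetric" if params.boundary == "symmetric" else "wrap"
    padded = np.pad(np.abs(plane), half, mode=pad_mode)
    r, c = row + half, col + half
    return float(padded[r - half : r + half + 1, c - half : c + half + 1].max())


def window_max_plane(plane, params: ShrinkageParams) -> np.ndarray:
    """Vectorized window maximum for every position of ``plane``."""
    mode = BOUNDARY_MODES[params.boundary]
    return ndimage.maximum_filter(np.abs(plane), size=params.window_size, mode=mode)


def shrink_coefficient(x: float, lambda_j: float, M_jk: float) -> float:
    """Three-branch neighborhood shrinkage of a single coefficient.

    - keep:   ``|x| >= lambda`` -> x unchanged;
    - shrink: ``|x| < lambda`` and window max ``M >= lambda`` ->
      ``x * (1 - (lambda - |x|) / (M - |x|))``, factor clamped to [0, 1];
    - zero:   otherwise (isolated small coefficient).

    Comparisons use ``|x|``, the sign of x is preserved, and the degenerate
    case ``M == |x| < lambda`` falls to the zero branch.
    """
    ax = abs(x)
    if ax >= lambda_j:
        return float(x)
    if M_jk >= lambda_j and M_jk > ax:
        factor = 1.0 - (lambda_j - ax) / (M_jk - ax)
        return float(x * min(max(factor, 0.0), 1.0))
    return 0.0


def shrink_plane(plane, lambda_j: float, window_maxima) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Vectorized shrinkage of a whole detail plane.

    Returns the shrunk plane and the (kept, shrunk, zeroed) branch counts.
    """
    x = np.asarray(plane, dtype=np.float64)
    ax = np.abs(x)
    M = np.asarray(window_maxima, dtype=np.float64)
    keep = ax >= lambda_j
    mid = ~keep & (M >= lambda_j) & (M > ax)
    out = np.zeros_like(x)
    out[keep] = x[keep]
    if np.any(mid):
        factor = 1.0 - (lambda_j - ax[mid]) / (M[mid] - ax[mid])
        out[mid] = x[mid] * np.clip(factor, 0.0, 1.0)
    counts = (int(keep.sum()), int(mid.sum()), int(x.size - keep.sum() - mid.sum()))
    return out, counts


def denoise_iwt(
    image,
    filters: FilterPair | str | None = None,
    scales: int = 3,
    params: ShrinkageParams | None = None,
    threshold_rule: str = "bayes",
    boundary: str = "symmetric",
):
    """End-to-end adaptive dyadic-wavelet denoising.

    Parameters
    ----------
    image : ImageGrid or 2-D array
    filters : FilterPair, wavelet name, or None (cubic B-spline)
    scales : int, default 3
        Decomposition depth J (default suits 256x256-class images).
    params : ShrinkageParams
        Window size (default 3) and boundary; the window boundary follows
        the transform's boundary mode.
    threshold_rule : {"bayes", "variance-ratio"}
    boundary : {"symmetric", "periodic"}

    Returns
    -------
    (denoised, diagnostics) — denoised matches the input type (ImageGrid in,
    ImageGrid out); diagnostics carry the noise model, thresholds and
    per-subband branch counts.
    """
    if filters is None:
        filters = bspline_filters()
    elif isinstance(filters, str):
        filters = get_filter_pair(filters)
    if params is None:
        params = ShrinkageParams(boundary=boundary)

    arr = as_array(image)
    decomp = dyadic_forward(arr, filters, scales, boundary)

    sigma = estimate_image_sigma(decomp, filters)
    sigma_sq = [propagate_noise_variance(sigma, filters, j) for j in range(1, scales + 1)]
    noise = NoiseModel(sigma, sigma_sq)

    L = arr.size  # undecimated: every subband is full size
    lambdas, betas, counts, new_details = [], [], [], []
    for j in range(1, scales + 1):
        lam_row, beta_row, count_row, plane_row = [], [], [], []
        for d in (1, 2):
            w = decomp.detail(j, d)
            sigma_sq_jd = propagate_noise_variance(sigma, filters, j, direction=d)
            beta = max(float(np.var(w)), _BETA_FLOOR)
            lam = compute_threshold(sigma_sq_jd, L, scales, beta, rule=threshold_rule)
            maxima = window_max_plane(w, params)
            shrunk, c = shrink_plane(w, lam, maxima)
            lam_row.append(lam)
            beta_row.append(beta)
            count_row.append(c)
            plane_row.append(shrunk)
        lambdas.append(lam_row)
        betas.append(beta_row)
        counts.append(count_row)
        new_details.append((plane_row[0], plane_row[1]))

    shrunk_decomp = DyadicDecomposition(new_details, decomp.approximation)
    out = dyadic_inverse(shrunk_decomp, filters, boundary)

    thresholds = ThresholdSet(lambdas, [L] * scales, betas, scales)
    diag = DenoiseDiagnostics(noise, thresholds, counts)
    if isinstance(image, ImageGrid):
        return image.with_values(out), diag
    return out, diag


class IWTDenoiser:
    """Adaptive dyadic-wavelet image denoiser, scikit-learn style.

    The estimator is stateless across images: ``transform`` adapts the noise
    model and thresholds to each image it denoises. ``fit`` validates the
    parameters and records the noise model and thresholds estimated on the
    given image in fitted attributes, so ``fit(X).transform(X)`` exposes the
    full diagnostics of the image it denoises.

    Parameters
    ----------
    wavelet : str, default "bspline"
        Dyadic filter bank ("bspline" or "haar").
    scales : int, default 3
        Decomposition depth J.
    window : int, default 3
        Odd side length of the neighborhood-maximum window.
    threshold_rule : {"bayes", "variance-ratio"}, default "bayes"
    boundary : {"symmetric", "periodic"}, default "symmetric"

    Attributes
    ----------
    noise_model_ : NoiseModel
    thresholds_ : ThresholdSet
    diagnostics_ : DenoiseDiagnostics
    """

    def __init__(self, wavelet="bspline", scales=3, window=3,
                 threshold_rule="bayes", boundary="symmetric"):
        self.wavelet = wavelet
        self.scales = scales
        self.window = window
        self.threshold_rule = threshold_rule
        self.boundary = boundary

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep=True):
        return {
            "wavelet": self.wavelet,
            "scales": self.scales,
            "window": self.window,
            "threshold_rule": self.threshold_rule,
            "boundary": self.boundary,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for {type(self).__name__}")
            setattr(self, key, value)
        return self

    def __repr__(self):
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"

    # ---------------------------------------------------------------------
    def _denoise(self, X):
        params = ShrinkageParams(window_size=self.window, boundary=self.boundary)
        return denoise_iwt(
            X,
            filters=self.wavelet,
            scales=self.scales,
            params=params,
            threshold_rule=self.threshold_rule,
            boundary=self.boundary,
        )

    def fit(self, X, y=None):
        """Estimate the noise model and thresholds for image ``X``."""
        _, diag = self._denoise(X)
        self.noise_model_ = diag.noise_model
        self.thresholds_ = diag.thresholds
        self.diagnostics_ = diag
        return self

    def transform(self, X):
        """Denoise image ``X`` (2-D array or ImageGrid), refreshing the
        diagnostics attributes for this image."""
        out, diag = self._denoise(X)
        self.noise_model_ = diag.noise_model
        self.thresholds_ = diag.thresholds
        self.diagnostics_ = diag
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
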