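import numpy as np
import pytest

from dyashrink import NoiseSpec, PhantomSpec, add_noise, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def phantom_pair():
    """(clean, noisy) 64x64 phantom at sigma=15, fixed seed."""
    clean = make_phantom(PhantomSpec(64, 64, (0.0, 255.0), 6, seed=7))
    noisy = add_noise(clean, NoiseSpec("gaussian", 15.0, seed=11))
    return clean, noisy


def brute_correlate1d(x, taps, center, axis, boundary):
    """Independent direct correlation: pad, then an explicit tap loop.

    y[i] = sum_k taps[k] * x[i + k - center] with 'symmetric' or 'periodic'
    out-of-range handling.
    """
    x = np.asarray(x, dtype=np.float64)
    taps = np.asarray(taps, dtype=np.float64)
    pad_mode = {"symmetric": "symmetric", "periodic": "wrap"}[boundary]
    n = taps.size
    before, after = center, n - 1 - center
    pad = [(0, 0), (0, 0)]
    pad[axis] = (before, after)
    xp = np.pad(x, pad, mode=pad_mode)
    out = np.zeros_like(x)
    for k in range(n):
        sl = [slice(None), slice(None)]
        sl[axis] = slice(k, k + x.shape[axis])
        out += taps[k] * xp[tuple(sl)]
    return out


def brute_mean_filter(x, kernel):
    """Double-loop neighborhood mean with symmetric boundary."""
    x = np.asarray(x, dtype=np.float64)
    half = kernel // 2
    xp = np.pad(x, half, mode="symmetric")
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            out[i, j] = xp[i : i + kernel, j : j + kernel].mean()
    return out


def brute_mse(a, b):
    """Double-loop mean squared error."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return total / (a.shape[0] * a.shape[1])
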