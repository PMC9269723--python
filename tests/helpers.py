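"""Independent oracle implementations used by the test suite.

Each function here reimplements, from first principles and without
touching the package's own code paths, an operation the pipeline
performs; tests assert agreement between the two routes.
"""

from itertools import product

import numpy as np


# ---------------------------------------------------------------------------
# rotations


def quat_to_matrix(q):
    """Scalar-first unit quaternion -> 3x3 rotation matrix (textbook formula)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def random_unit_quats(n, seed):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# PCHIP (Fritsch-Carlson monotone cubic)


def fritsch_carlson_derivatives(x, y):
    h = np.diff(x)
    m = np.diff(y) / h
    n = len(x)
    d = np.zeros(n)
    for k in range(1, n - 1):
        if m[k - 1] * m[k] <= 0:
            d[k] = 0.0
        else:
            w1 = 2 * h[k] + h[k - 1]
            w2 = h[k] + 2 * h[k - 1]
            d[k] = (w1 + w2) / (w1 / m[k - 1] + w2 / m[k])

    def edge(h0, h1, m0, m1):
        dd = ((2 * h0 + h1) * m0 - h0 * m1) / (h0 + h1)
        if np.sign(dd) != np.sign(m0):
            return 0.0
        if np.sign(m0) != np.sign(m1) and abs(dd) > 3 * abs(m0):
            return 3 * m0
        return dd

    d[0] = edge(h[0], h[1], m[0], m[1])
    d[-1] = edge(h[-1], h[-2], m[-1], m[-2])
    return d


def pchip_oracle(y, n_points=100):
    """Monotone cubic Hermite resampling, independent implementation."""
    y = np.asarray(y, dtype=float)
    x = np.linspace(0.0, 1.0, len(y))
    d = fritsch_carlson_derivatives(x, y)
    xq = np.linspace(0.0, 1.0, n_points)
    idx = np.clip(np.searchsorted(x, xq) - 1, 0, len(x) - 2)
    h = x[idx + 1] - x[idx]
    t = (xq - x[idx]) / h
    h00 = 2 * t**3 - 3 * t**2 + 1
    h10 = t**3 - 2 * t**2 + t
    h01 = -2 * t**3 + 3 * t**2
    h11 = t**3 - t**2
    return h00 * y[idx] + h10 * h * d[idx] + h01 * y[idx + 1] + h11 * h * d[idx + 1]


# ---------------------------------------------------------------------------
# SPARC arc length


def arc_length_oracle(freqs, mags, fc, refine=10):
    """Numerical integration of the spectral arc-length functional.

    Integrates sqrt((1/fc)^2 + V'(f)^2) df over [0, fc] with the
    trapezoidal rule on a ``refine``-times finer grid of the
    piecewise-linear spectrum.
    """
    freqs = np.asarray(freqs, float)
    mags = np.asarray(mags, float)
    total = 0.0
    for a, b, ma, mb in zip(freqs[:-1], freqs[1:], mags[:-1], mags[1:]):
        grid = np.linspace(a, b, refine + 1)
        v = np.interp(grid, [a, b], [ma, mb])
        slope = np.gradient(v, grid)
        total += np.trapezoid(np.sqrt((1.0 / fc) ** 2 + slope**2), grid)
    return total


def dtft_magnitudes(v, freqs, fs):
    """Brute-force discrete-time Fourier transform magnitudes (no FFT)."""
    n = np.arange(len(v))
    expo = np.exp(-2j * np.pi * np.outer(freqs, n) / fs)
    return np.abs(expo @ np.asarray(v, dtype=float))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank by full enumeration


def wilcoxon_enumeration_p(x, y):
    """Two-sided exact signed-rank p-value by brute-force enumeration."""
    from scipy.stats import rankdata

    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0.0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    dist = []
    for signs in product([0, 1], repeat=n):
        dist.append(np.dot(signs, ranks))
    dist = np.asarray(dist)
    eps = 1e-9
    p_ge = np.mean(dist >= w - eps)
    p_le = np.mean(dist <= w + eps)
    return min(1.0, 2.0 * min(p_ge, p_le))
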