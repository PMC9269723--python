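"""Movement smoothness metrics: spectral arc length and log dimensionless jerk.

SPARC (spectral arc length) measures smoothness as minus the arc length
of the max-normalized Fourier magnitude spectrum V̂(f) of a signal up to
a cutoff frequency fc (10 Hz here), with the frequency axis scaled by
1/fc:

    SPARC = -∫₀^fc sqrt( (1/fc)² + (dV̂/df)² ) df

Since the (1/fc) df terms alone integrate to exactly 1 over [0, fc],
SPARC <= -1 always, with -1 attained only by a spectrum flat at its own
maximum (in particular a pure DC spectrum); more negative means a more
fragmented spectrum, i.e. a less smooth movement.

LDLJ-A (log dimensionless jerk on acceleration) integrates the squared
jerk of the gravity-free acceleration vector over a stride [t1, t2],
made dimensionless with the segment duration and the peak magnitude of
the mean-removed acceleration:

    LDLJ = -ln( (t2-t1)/a_peak² · ∫ ||da/dt||² dt )

Both metrics are computed per stride on raw-time samples (not on the
100-point time-normalized strides): smoothness depends on true time and
the spectral axis is in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .datamodel import GRAVITY, SensorRecording, ValidationError

DEFAULT_SPARC_FC = 10.0

__all__ = [
    "SparcParams",
    "sparc",
    "sparc_gyro_norm",
    "ldlj_a",
    "ldlj_per_stride",
    "DegenerateSignalError",
]


class DegenerateSignalError(ValidationError):
    pass


@dataclass(frozen=True)
class SparcParams:
    """SPARC settings: cutoff fc (Hz) and zero-padding policy.

    The spectrum is zero-padded to the next power of two at least
    ``pad_factor`` times the segment length, then one linearly
    interpolated sample is appended at exactly fc so the arc covers
    [0, fc] without a gap; magnitudes are normalized by their maximum.
    """

    fc: float = DEFAULT_SPARC_FC
    pad_factor: int = 4

    def __post_init__(self):
        if not self.fc > 0:
            raise ValidationError("fc must be > 0")


def spectrum_grid(v: np.ndarray, fs: float, params: SparcParams):
    """Normalized magnitude spectrum samples on [0, fc] (freqs, magnitudes)."""
    n = len(v)
    nfft = int(2 ** np.ceil(np.log2(max(params.pad_factor * n, 16))))
    mag = np.abs(np.fft.rfft(v, nfft))
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    mmax = mag.max()
    if mmax == 0.0:
        raise DegenerateSignalError("degenerate spectrum (all-zero signal)")
    mag = mag / mmax
    keep = f <= params.fc
    fk, mk = f[keep], mag[keep]
    if fk[-1] < params.fc:
        # close the [0, fc] interval so the (1/fc) df terms sum to exactly 1
        mk = np.append(mk, np.interp(params.fc, f, mag))
        fk = np.append(fk, params.fc)
    return fk, mk


def sparc(v, fs: float, params: SparcParams | None = None) -> float:
    """Spectral arc length of a 1-D signal (dimensionless, <= -1).

    Scale-invariant (max normalization cancels amplitude).  A constant
    signal has spectral content at DC only, where the continuous
    integrand reduces to 1/fc: the limit value -1 is returned.  An
    identically zero signal has no spectrum to normalize and raises
    :class:`DegenerateSignalError`.
    """
    params = params or SparcParams()
    v = np.asarray(v, dtype=float)
    if len(v) < 8:
        raise ValidationError("segment too short for SPARC (need >= 8 samples)")
    if fs <= 2 * params.fc:
        raise ValidationError(f"fc={params.fc} Hz above Nyquist at fs={fs} Hz")
    if np.all(v == 0.0):
        raise DegenerateSignalError("degenerate spectrum (all-zero signal)")
    if np.ptp(v) == 0.0:
        return -1.0
    fk, mk = spectrum_grid(v, fs, params)
    df = np.diff(fk) / params.fc
    return float(-np.sum(np.sqrt(df**2 + np.diff(mk) ** 2)))


def sparc_batch(segments: np.ndarray, fs: float,
                params: SparcParams | None = None) -> np.ndarray:
    """Column-wise SPARC of a (T, C) multi-channel segment (one FFT pass).

    Matches :func:`sparc` per column; constant columns yield -1 and
    all-zero columns NaN (a batch should not fail on one dead channel).
    """
    params = params or SparcParams()
    seg = np.atleast_2d(np.asarray(segments, dtype=float))
    n, n_cols = seg.shape
    if n < 8:
        raise ValidationError("segment too short for SPARC (need >= 8 samples)")
    if fs <= 2 * params.fc:
        raise ValidationError(f"fc={params.fc} Hz above Nyquist at fs={fs} Hz")
    nfft = int(2 ** np.ceil(np.log2(max(params.pad_factor * n, 16))))
    mag = np.abs(np.fft.rfft(seg, nfft, axis=0))
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    n_keep = int(np.searchsorted(f, params.fc, side="right"))
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = mag / mag.max(axis=0, keepdims=True)
    fk = f[:n_keep]
    mk = mag[:n_keep]
    if fk[-1] < params.fc:
        # interpolated sample at exactly fc closes the [0, fc] interval
        w = (params.fc - f[n_keep - 1]) / (f[n_keep] - f[n_keep - 1])
        m_fc = (1 - w) * mag[n_keep - 1] + w * mag[n_keep]
        fk = np.append(fk, params.fc)
        mk = np.vstack([mk, m_fc])
    df = (np.diff(fk) / params.fc)[:, None]
    out = -np.sum(np.sqrt(df**2 + np.diff(mk, axis=0) ** 2), axis=0)
    constant = np.ptp(seg, axis=0) == 0.0
    if constant.any():
        out[constant] = np.where(np.all(seg == 0.0, axis=0)[constant], np.nan, -1.0)
    return out


def sparc_gyro_norm(rec: SensorRecording, boundaries,
                    params: SparcParams | None = None) -> np.ndarray:
    """Per-stride SPARC of the angular velocity norm (rotation-invariant)."""
    norm = np.linalg.norm(rec.gyro, axis=1)
    return np.array([
        sparc(norm[a:b], rec.fs, params) for a, b in boundaries.stride_windows()
    ])


def _global_acc(acc, quat):
    a_g = Rotation.from_quat(np.asarray(quat, float), scalar_first=True).apply(
        np.asarray(acc, float))
    a_g[:, 2] -= GRAVITY
    return a_g


def ldlj_a(acc, quat, fs: float, segment: tuple[float, float]) -> float:
    """Log dimensionless jerk of the gravity-free acceleration vector.

    ``segment`` is (t1, t2) in seconds relative to the start of ``acc``.
    Jerk is computed by central differences (one-sided at the segment
    edges) and integrated with the trapezoidal rule.  Raises
    :class:`DegenerateSignalError` for constant acceleration (zero peak
    or zero jerk integral).
    """
    t1, t2 = segment
    if not t2 > t1:
        raise ValidationError("segment must satisfy t2 > t1")
    i1, i2 = int(round(t1 * fs)), int(round(t2 * fs))
    a_g = _global_acc(acc, quat)[i1:i2]
    if a_g.shape[0] < 8:
        raise ValidationError("segment too short for LDLJ (need >= 8 samples)")
    duration = (a_g.shape[0] - 1) / fs
    centered = a_g - a_g.mean(axis=0)
    apeak = float(np.linalg.norm(centered, axis=1).max())
    jerk = np.gradient(a_g, 1.0 / fs, axis=0)
    integral = float(np.trapezoid(np.sum(jerk**2, axis=1), dx=1.0 / fs))
    if apeak == 0.0 or integral == 0.0:
        raise DegenerateSignalError("constant acceleration: LDLJ undefined")
    return float(-np.log(duration / apeak**2 * integral))


def ldlj_per_stride(rec: SensorRecording, boundaries) -> np.ndarray:
    """LDLJ-A for every stride window of a recording."""
    return np.array([
        ldlj_a(rec.acc, rec.quat, rec.fs, (a / rec.fs, b / rec.fs))
        for a, b in boundaries.stride_windows()
    ])
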