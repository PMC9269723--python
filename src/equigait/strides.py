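"""Stride time-normalization, reference strides, and CC/RMSD indicators.

Each stride (a variable-length window between consecutive stride peaks)
is resampled to 100 points with monotone piecewise-cubic (PCHIP)
interpolation.  Strides of a run are grouped per channel; the group's
reference stride is the one minimizing the RMSD to the pointwise mean.
Every stride is then compared against a reference with the Pearson
correlation coefficient (CC, shape similarity) and the root mean square
deviation (RMSD, amplitude difference, channel units):

* ``intra_before`` / ``intra_after`` — strides vs their own run's
  reference (the null condition; the reference itself is excluded from
  its own comparison set);
* ``inter`` — after-run strides vs the before-run reference (the
  training-effect condition); the symmetric direction is stored as
  ``inter_sym`` but not screened by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .datamodel import ValidationError

N_POINTS = 100

#: comparison scopes for CC/RMSD; per-run scopes for smoothness/duration
SCOPE_INTRA_BEFORE = "intra_before"
SCOPE_INTRA_AFTER = "intra_after"
SCOPE_INTER = "inter"
SCOPE_INTER_SYM = "inter_sym"
SCOPE_BEFORE = "before"
SCOPE_AFTER = "after"

__all__ = [
    "N_POINTS",
    "IndicatorRecord",
    "NormalizedStrideGroup",
    "normalize_stride",
    "normalize_strides",
    "build_group",
    "compare",
    "run_indicators",
]


@dataclass(frozen=True)
class IndicatorRecord:
    """One (horse, gait, sensor, channel, indicator, scope) value.

    ``indicator`` is one of CC, RMSD, SPARC, LDLJ, stride_duration;
    ``scope`` identifies the comparison (intra/inter) for CC/RMSD or the
    run (before/after) for per-run indicators.  ``value`` is
    dimensionless for CC/SPARC/LDLJ, in channel units for RMSD, seconds
    for stride_duration.
    """

    horse: str
    gait: str
    sensor: str
    side: str
    channel: str
    indicator: str
    scope: str
    run: str
    value: float


def normalize_stride(stride, n_points: int = N_POINTS) -> np.ndarray:
    """Resample one stride to ``n_points`` samples by PCHIP interpolation.

    Monotone piecewise-cubic Hermite interpolation onto equally spaced
    points over [0, 100%] of the stride; endpoints are preserved
    exactly and no overshoot is introduced.
    """
    y = np.asarray(stride, dtype=float)
    if y.ndim != 1:
        raise ValidationError("normalize_stride expects a 1-D series")
    if len(y) < 4:
        raise ValidationError(f"stride too short to normalize ({len(y)} samples)")
    x = np.linspace(0.0, 1.0, len(y))
    return PchipInterpolator(x, y)(np.linspace(0.0, 1.0, n_points))


def normalize_strides(segments: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Resample a (T, C) multi-channel stride to (n_points, C) in one pass."""
    y = np.asarray(segments, dtype=float)
    if y.shape[0] < 4:
        raise ValidationError(f"stride too short to normalize ({y.shape[0]} samples)")
    x = np.linspace(0.0, 1.0, y.shape[0])
    return PchipInterpolator(x, y, axis=0)(np.linspace(0.0, 1.0, n_points))


def _rmsd_rows(rows: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean((rows - ref[None, :]) ** 2, axis=1))


@dataclass
class NormalizedStrideGroup:
    """All time-normalized strides of one (run, sensor, channel).

    ``strides`` is (N, 100); ``ref_index`` is the row minimizing RMSD to
    the pointwise mean (ties broken to the lowest index).
    """

    horse: str
    gait: str
    run: str
    sensor: str
    side: str
    channel: str
    strides: np.ndarray
    mean_stride: np.ndarray = None
    ref_index: int = -1

    def __post_init__(self):
        self.strides = np.atleast_2d(np.asarray(self.strides, dtype=float))
        if self.strides.shape[0] < 2:
            raise ValidationError("stride group needs at least 2 strides")
        if self.mean_stride is None:
            self.mean_stride = self.strides.mean(axis=0)
        if self.ref_index < 0:
            self.ref_index = int(np.argmin(_rmsd_rows(self.strides, self.mean_stride)))

    @property
    def n_strides(self) -> int:
        return self.strides.shape[0]

    @property
    def reference(self) -> np.ndarray:
        return self.strides[self.ref_index]


def build_group(strides, *, horse="", gait="", run="", sensor="", side="",
                channel="") -> NormalizedStrideGroup:
    """Group normalized strides and select the reference stride."""
    strides = np.asarray(strides, dtype=float)
    if strides.ndim != 2 or strides.shape[1] != N_POINTS:
        raise ValidationError(
            f"expected an (N, {N_POINTS}) stride matrix, got {strides.shape}"
        )
    return NormalizedStrideGroup(
        horse=horse, gait=gait, run=run, sensor=sensor, side=side,
        channel=channel, strides=strides,
    )


def compare(stride, reference) -> tuple[float, float]:
    """Pearson CC and RMSD between a stride and a reference.

    CC is undefined (returned as NaN) when either series has zero
    variance; RMSD is always computed.
    """
    a = np.asarray(stride, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan"), rmsd
    cc = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return min(1.0, max(-1.0, cc)), rmsd


def compare_rows(rows: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`compare` of every row against one reference."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ref = np.asarray(ref, dtype=float)
    rmsd = np.sqrt(np.mean((rows - ref[None, :]) ** 2, axis=1))
    rc = rows - rows.mean(axis=1, keepdims=True)
    bc = ref - ref.mean()
    sa = rows.std(axis=1)
    sb = ref.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.mean(rc * bc[None, :], axis=1) / (sa * sb)
    cc = np.where((sa == 0) | (sb == 0), np.nan, np.clip(cc, -1.0, 1.0))
    return cc, rmsd


def _mean_compare(rows: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    ccs, rmsds = compare_rows(rows, ref)
    cc = float(np.nanmean(ccs)) if not np.all(np.isnan(ccs)) else float("nan")
    return cc, float(np.mean(rmsds))


def run_indicators(before: NormalizedStrideGroup,
                   after: NormalizedStrideGroup) -> list:
    """CC/RMSD indicator records for one channel's before/after groups.

    Emits six records: CC and RMSD for scopes intra_before, intra_after,
    inter (after-strides vs before-reference), plus the symmetric
    inter_sym direction.
    """
    for attr in ("horse", "gait", "sensor", "side", "channel"):
        if getattr(before, attr) != getattr(after, attr):
            raise ValidationError(
                f"group mismatch on {attr}: "
                f"{getattr(before, attr)!r} vs {getattr(after, attr)!r}"
            )
    records = []

    def emit(scope, run, cc, rmsd):
        base = dict(horse=before.horse, gait=before.gait, sensor=before.sensor,
                    side=before.side, channel=before.channel, scope=scope, run=run)
        records.append(IndicatorRecord(indicator="CC", value=cc, **base))
        records.append(IndicatorRecord(indicator="RMSD", value=rmsd, **base))

    intra_b = np.delete(before.strides, before.ref_index, axis=0)
    intra_a = np.delete(after.strides, after.ref_index, axis=0)
    emit(SCOPE_INTRA_BEFORE, SCOPE_BEFORE, *_mean_compare(intra_b, before.reference))
    emit(SCOPE_INTRA_AFTER, SCOPE_AFTER, *_mean_compare(intra_a, after.reference))
    emit(SCOPE_INTER, SCOPE_AFTER, *_mean_compare(after.strides, before.reference))
    emit(SCOPE_INTER_SYM, SCOPE_BEFORE, *_mean_compare(before.strides, after.reference))
    return records
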