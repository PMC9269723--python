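"""Paired Wilcoxon screening of indicators for a training-session effect.

Every indicator key (gait, sensor, channel, indicator type) is tested
across horses with a two-sided Wilcoxon signed-rank test on paired
per-horse values:

* CC and RMSD: intra-run (before) vs inter-run values — the intra-run
  comparison is the null condition, since within a run the training
  session cannot have caused differences;
* SPARC, LDLJ and stride duration: before-run vs after-run values.

The exact null distribution (enumeration over all sign assignments of
the ranked absolute differences) is used for n <= 15 pairs; above that,
the normal approximation with continuity and tie corrections.  Zero
differences are dropped (Wilcoxon's original treatment); ties among
absolute differences receive average ranks.  Significance is banded at
0.01 and 0.05 with no multiple-testing correction by default; CC keys
are additionally retained only when the mean pre-training (intra-run
before) CC exceeds 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

ALPHA_DEFAULT = 0.05
CC_RETENTION_THRESHOLD = 0.80
EXACT_MAX_N = 15

#: which scopes are paired per indicator type: (null/baseline, effect)
SCOPE_PAIRS = {
    "CC": ("intra_before", "inter"),
    "RMSD": ("intra_before", "inter"),
    "SPARC": ("before", "after"),
    "LDLJ": ("before", "after"),
    "stride_duration": ("before", "after"),
}

__all__ = [
    "WilcoxonResult",
    "ScreenResult",
    "wilcoxon_paired",
    "screen_indicators",
    "apply_cc_retention",
    "report_tables",
    "format_mean_sd",
]


class WilcoxonResult(NamedTuple):
    p_value: float
    direction: str  # how y compares to x: "increase", "decrease" or "none"
    n_used: int  # pairs after dropping zero differences
    statistic: float  # W+ (rank sum of positive x - y differences)
    degenerate: bool  # all differences zero


def _exact_p(ranks: np.ndarray, w: float) -> float:
    """Two-sided exact p by enumeration over all 2^n sign assignments."""
    n = len(ranks)
    signs = (np.arange(1 << n)[:, None] >> np.arange(n)) & 1
    dist = signs @ ranks
    eps = 1e-9
    p_ge = float(np.mean(dist >= w - eps))
    p_le = float(np.mean(dist <= w + eps))
    return min(1.0, 2.0 * min(p_ge, p_le))


def _approx_p(ranks: np.ndarray, w: float) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return 1.0
    d = w - mu
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var) if d != 0 else 0.0
    return min(1.0, 2.0 * sstats.norm.sf(abs(z)))


def wilcoxon_paired(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Pairs containing NaN are removed; at least 5 complete pairs are
    required.  Zero differences are dropped before ranking.  The
    reported direction describes y relative to x (sign of the median
    difference): with all effect-free pairs equal, the result is
    degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError(f"insufficient pairs for Wilcoxon test (n={len(x)})")
    d = x - y
    med = float(np.median(d))
    direction = "decrease" if med > 0 else ("increase" if med < 0 else "none")
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(1.0, "none", 0, 0.0, True)
    ranks = sstats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_p(ranks, w)
    else:
        p = _approx_p(ranks, w)
    return WilcoxonResult(p, direction, n, w, False)


@dataclass
class ScreenResult:
    """Screening outcome for one indicator key."""

    gait: str
    sensor: str
    channel: str
    indicator: str
    n_pairs: int
    p_value: float
    scope_x: str
    scope_y: str
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    direction: str
    degenerate: bool = False
    significant: bool = False
    band: str = "ns"
    retained: bool = False

    @property
    def key(self) -> tuple:
        return (self.gait, self.sensor, self.channel, self.indicator)


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "horse": [r.horse for r in records],
            "gait": [r.gait for r in records],
            "sensor": [r.sensor for r in records],
            "side": [r.side for r in records],
            "channel": [r.channel for r in records],
            "indicator": [r.indicator for r in records],
            "scope": [r.scope for r in records],
            "value": [r.value for r in records],
        }
    )


def screen_indicators(records, alpha: float = ALPHA_DEFAULT,
                      pool_sides: bool = True, bh: bool = False,
                      min_pairs: int = 5) -> list:
    """Screen all indicator keys with paired Wilcoxon tests.

    Left/right cannon sensors are pooled by per-horse averaging before
    testing (``pool_sides=False`` keeps them separate, the sensor label
    then carrying the side).  Keys missing one of their two scopes, or
    with fewer than ``min_pairs`` complete horse pairs, are skipped.
    ``bh=True`` applies Benjamini-Hochberg control of the false
    discovery rate at ``alpha`` instead of raw-p thresholding (off by
    default).
    """
    df = _records_frame(list(records))
    if pool_sides:
        df = (
            df.groupby(["horse", "gait", "sensor", "channel", "indicator", "scope"],
                       as_index=False)["value"].mean()
        )
    else:
        df = df.assign(
            sensor=np.where(df["side"].isin(["left", "right"]),
                            df["sensor"] + "_" + df["side"].str[0].str.upper(),
                            df["sensor"])
        )

    wide_all = df.pivot_table(
        index=["gait", "sensor", "channel", "indicator", "horse"],
        columns="scope", values="value", aggfunc="mean",
    )
    results = []
    for (gait, sensor, channel, indicator), wide in wide_all.groupby(
        level=["gait", "sensor", "channel", "indicator"]
    ):
        pair = SCOPE_PAIRS.get(indicator)
        if pair is None:
            continue
        scope_x, scope_y = pair
        if scope_x not in wide.columns or scope_y not in wide.columns:
            continue
        x = wide[scope_x].to_numpy()
        y = wide[scope_y].to_numpy()
        complete = ~(np.isnan(x) | np.isnan(y))
        if complete.sum() < min_pairs:
            continue
        res = wilcoxon_paired(x[complete], y[complete])
        results.append(
            ScreenResult(
                gait=gait, sensor=sensor, channel=channel, indicator=indicator,
                n_pairs=int(complete.sum()), p_value=res.p_value,
                scope_x=scope_x, scope_y=scope_y,
                mean_x=float(np.nanmean(x)), sd_x=float(np.nanstd(x, ddof=1)),
                mean_y=float(np.nanmean(y)), sd_y=float(np.nanstd(y, ddof=1)),
                direction=res.direction, degenerate=res.degenerate,
            )
        )

    pvals = np.array([r.p_value for r in results])
    if bh and len(pvals):
        adjusted = sstats.false_discovery_control(pvals, method="bh")
        sig = adjusted <= alpha
    else:
        sig = pvals < alpha
    for r, s in zip(results, sig):
        r.significant = bool(s)
        if r.p_value < 0.01:
            r.band = "p<0.01"
        elif r.p_value < alpha:
            r.band = "0.01<=p<0.05"
        else:
            r.band = "ns"
    return apply_cc_retention(results)


def apply_cc_retention(results, records=None,
                       threshold: float = CC_RETENTION_THRESHOLD) -> list:
    """Set retention flags: only reliably repeatable CC keys survive.

    A CC key is retained iff it is significant *and* its mean
    pre-training (intra-run before) CC across horses exceeds the
    threshold; other indicator types are retained iff significant.
    Retention never adds keys: retained is a subset of significant.
    """
    for r in results:
        if r.indicator == "CC":
            r.retained = bool(r.significant and r.mean_x > threshold)
        else:
            r.retained = bool(r.significant)
    return results


def format_mean_sd(mean: float, sd: float) -> str:
    """Two-decimal "mean (sd)" formatting, e.g. ``0.92 (0.04)``."""

    def fmt(v: float) -> str:
        s = f"{v:.2f}"
        if "." in s:
            s = s.rstrip("0").rstrip(".")
        return "0" if s == "-0" else s

    return f"{fmt(mean)} ({fmt(sd)})"


def report_tables(results) -> dict:
    """Ranked report tables of retained indicators plus sensor counts.

    Returns a dict with per-indicator-type DataFrames (``CC``, ``SPARC``,
    ``RMSD``, ``LDLJ``, ``stride_duration``) of retained keys sorted by
    p-value, and ``sensor_counts``: the number of significant indicators
    per sensor location and gait.
    """
    tables = {}
    for ind in SCOPE_PAIRS:
        rows = [r for r in results if r.indicator == ind and r.retained]
        rows.sort(key=lambda r: (r.p_value, r.sensor, r.channel))
        tables[ind] = pd.DataFrame(
            [
                {
                    "gait": r.gait, "channel": r.channel, "sensor": r.sensor,
                    "p": round(r.p_value, 3),
                    r.scope_x: format_mean_sd(r.mean_x, r.sd_x),
                    r.scope_y: format_mean_sd(r.mean_y, r.sd_y),
                    "direction": r.direction,
                }
                for r in rows
            ],
            columns=["gait", "channel", "sensor", "p",
                     SCOPE_PAIRS[ind][0], SCOPE_PAIRS[ind][1], "direction"],
        )
    sig = [r for r in results if r.significant]
    counts = pd.DataFrame([{"sensor": r.sensor, "gait": r.gait} for r in sig])
    if len(counts):
        sensor_counts = (
            counts.value_counts(["sensor", "gait"]).rename("n_significant")
            .reset_index().sort_values(["sensor", "gait"]).reset_index(drop=True)
        )
    else:
        sensor_counts = pd.DataFrame(columns=["sensor", "gait", "n_significant"])
    tables["sensor_counts"] = sensor_counts
    return tables
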