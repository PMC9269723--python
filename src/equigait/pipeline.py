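"""End-to-end orchestration: synthesize/load -> derive -> segment ->
compare -> smoothness -> screen, under a single config with a seed.

The pipeline consumes before/after session pairs (synthetic or loaded
from recording containers), produces the full indicator table, screens
it, and writes a report bundle: ``indicators.csv``, per-indicator-type
screening tables, ``sensor_counts.csv``, ``qc.csv`` and a run manifest.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as egio
from .datamodel import Gait, Session, ValidationError
from .kinematics import derive_channels
from .segmentation import detect_strides, lowpass_butterworth, qc_report
from .smoothness import SparcParams, ldlj_per_stride, sparc_batch, sparc_gyro_norm
from .stats import report_tables, screen_indicators
from .strides import (
    IndicatorRecord,
    NormalizedStrideGroup,
    SCOPE_AFTER,
    SCOPE_BEFORE,
    normalize_strides,
    run_indicators,
)
from .synthetic import FatigueEffect, HerdSpec, default_template, generate_herd

logger = logging.getLogger("equigait")

__all__ = ["PipelineConfig", "PipelineError", "compute_session_features",
           "pair_indicators", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending entity."""


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's reference values.

    fc_filter 3 Hz / filter_order 4 / min_sep 0.75 for segmentation,
    n_points 100 for time normalization, fc_sparc 10 Hz for smoothness,
    alpha 0.05 and cc_retention 0.80 for screening.
    """

    mode: str = "synthetic"  # or "directory"
    input_dir: str | None = None
    out_dir: str = "equigait_out"
    seed: int = 0
    gaits: tuple = ("trot", "canter")
    # synthetic herd
    n_horses: int = 10
    passages_per_run: int = 2
    duration_s: float = 10.0
    fs: float = 128.0
    noise_sd_acc: float = 0.5
    noise_sd_gyro: float = 0.05
    timing_jitter: float = 0.02
    shape_delta: float = 0.0
    amp_delta: float = 0.0
    roughness_delta: float = 0.0
    # stages
    fc_filter: float = 3.0
    filter_order: int = 4
    min_sep: float = 0.75
    n_points: int = 100
    fc_sparc: float = 10.0
    alpha: float = 0.05
    cc_retention: float = 0.80
    pool_sides: bool = True
    bh: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "gaits" in raw:
            raw["gaits"] = tuple(raw["gaits"])
        defaults = cls()
        for key, value in raw.items():
            if value != getattr(defaults, key):
                logger.info("config override: %s = %r", key, value)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gaits"] = list(d["gaits"])
        return d


def _stage(name: str, entity: str = ""):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                where = f" ({entity})" if entity else ""
                raise PipelineError(f"stage {name}{where}: {exc}") from exc
            return False

    return _Ctx()


def compute_session_features(session: Session, cfg: PipelineConfig) -> dict:
    """Segment one session and collect per-channel strides and smoothness.

    Returns normalized stride matrices per (sensor key, channel), per-
    stride SPARC/LDLJ values, stride durations, and per-passage QC
    summaries.  Strides are pooled across the session's passages.
    """
    sparc_params = SparcParams(fc=cfg.fc_sparc)
    strides: dict = {}
    sparc_vals: dict = {}
    ldlj_vals: dict = {}
    durations: list = []
    qc = []
    ent = f"{session.horse_id}/{session.gait.value}/{session.run.value}"
    for p_idx, passage in enumerate(session.passages):
        if "ST" not in passage:
            raise PipelineError(
                f"stage segmentation ({ent}): passage {p_idx} lacks the sternum sensor")
        with _stage("segmentation", f"{ent} passage {p_idx}"):
            st_channels = derive_channels(passage["ST"])
            filtered = lowpass_butterworth(
                st_channels["acc_vert"], passage["ST"].fs,
                fc=cfg.fc_filter, order=cfg.filter_order)
            boundaries = detect_strides(filtered, passage["ST"].fs,
                                        min_sep_fraction=cfg.min_sep)
        qc.append(qc_report(boundaries))
        windows = boundaries.stride_windows()
        if not windows:
            raise PipelineError(
                f"stage segmentation ({ent}): no usable strides in passage {p_idx}")
        durations.extend((b - a) / passage["ST"].fs for a, b in windows)
        for key in sorted(passage):
            rec = passage[key]
            with _stage("kinematics", f"{ent} {key}"):
                cs = derive_channels(rec) if key != "ST" else st_channels
            names = list(cs.channels)
            matrix = np.column_stack([cs[n] for n in names])
            with _stage("stride_comparison", f"{ent} {key}"):
                for a, b in windows:
                    norm = normalize_strides(matrix[a:b], cfg.n_points)
                    for j, name in enumerate(names):
                        strides.setdefault((key, name), []).append(norm[:, j])
            with _stage("smoothness", f"{ent} {key}"):
                for a, b in windows:
                    vals = sparc_batch(matrix[a:b], rec.fs, sparc_params)
                    for j, name in enumerate(names):
                        sparc_vals.setdefault((key, name), []).append(vals[j])
                for v in sparc_gyro_norm(rec, boundaries, sparc_params):
                    sparc_vals.setdefault((key, "gyro_norm"), []).append(v)
                for v in ldlj_per_stride(rec, boundaries):
                    ldlj_vals.setdefault((key, "acc_vector"), []).append(v)
    return {
        "strides": {k: np.asarray(v) for k, v in strides.items()},
        "sparc": {k: float(np.nanmean(v)) for k, v in sparc_vals.items()},
        "ldlj": {k: float(np.nanmean(v)) for k, v in ldlj_vals.items()},
        "stride_duration": float(np.mean(durations)),
        "qc": qc,
    }


def _split_key(key: str) -> tuple[str, str]:
    """Location key -> (sensor code, side label)."""
    if "_" in key:
        code, s = key.split("_")
        return code, {"L": "left", "R": "right"}[s]
    return key, "midline"


def pair_indicators(before: Session, after: Session,
                    cfg: PipelineConfig, qc_sink: list | None = None) -> list:
    """Full indicator records for one horse's before/after session pair.

    ``qc_sink``, if given, collects one per-passage QC row per session.
    """
    if (before.horse_id != after.horse_id or before.gait != after.gait):
        raise ValidationError("before/after sessions must match horse and gait")
    fb = compute_session_features(before, cfg)
    fa = compute_session_features(after, cfg)
    horse, gait = before.horse_id, before.gait.value
    if qc_sink is not None:
        for session, feats in ((before, fb), (after, fa)):
            for p_idx, q in enumerate(feats["qc"]):
                qc_sink.append({
                    "horse": horse, "gait": gait, "run": session.run.value,
                    "passage": p_idx, "n_peaks": q["n_peaks"],
                    "period_cv": q["period_cv"],
                    "period_median_s": q["period_median_s"],
                    "verdict": q["verdict"],
                })
    records = []
    for (key, channel), mat_b in fb["strides"].items():
        mat_a = fa["strides"].get((key, channel))
        if mat_a is None or len(mat_b) < 2 or len(mat_a) < 2:
            logger.warning("skipping %s/%s %s %s: too few strides",
                           horse, gait, key, channel)
            continue
        sensor, side = _split_key(key)
        gb = NormalizedStrideGroup(horse=horse, gait=gait, run="before",
                                   sensor=sensor, side=side, channel=channel,
                                   strides=mat_b)
        ga = NormalizedStrideGroup(horse=horse, gait=gait, run="after",
                                   sensor=sensor, side=side, channel=channel,
                                   strides=mat_a)
        records.extend(run_indicators(gb, ga))
    for name, scope, feats in (("before", SCOPE_BEFORE, fb), ("after", SCOPE_AFTER, fa)):
        for (key, channel), value in feats["sparc"].items():
            sensor, side = _split_key(key)
            records.append(IndicatorRecord(
                horse=horse, gait=gait, sensor=sensor, side=side, channel=channel,
                indicator="SPARC", scope=scope, run=name, value=value))
        for (key, channel), value in feats["ldlj"].items():
            sensor, side = _split_key(key)
            records.append(IndicatorRecord(
                horse=horse, gait=gait, sensor=sensor, side=side, channel=channel,
                indicator="LDLJ", scope=scope, run=name, value=value))
        records.append(IndicatorRecord(
            horse=horse, gait=gait, sensor="ST", side="midline", channel="time",
            indicator="stride_duration", scope=scope, run=name,
            value=feats["stride_duration"]))
    return records


def _herd_spec(cfg: PipelineConfig) -> HerdSpec:
    return HerdSpec(
        n_horses=cfg.n_horses, passages_per_run=cfg.passages_per_run,
        duration_s=cfg.duration_s, fs=cfg.fs, noise_sd_acc=cfg.noise_sd_acc,
        noise_sd_gyro=cfg.noise_sd_gyro, timing_jitter=cfg.timing_jitter,
        seed=cfg.seed,
    )


def _load_pairs(cfg: PipelineConfig) -> list:
    """Pair up sessions found in recording containers under input_dir."""
    root = Path(cfg.input_dir)
    sessions = []
    for entry in sorted(root.iterdir()):
        if entry.is_dir() and (entry / "session.json").exists():
            sessions.append(egio.load_recording(entry, format="csv"))
        elif entry.suffix in (".h5", ".hdf5"):
            sessions.append(egio.load_recording(entry, format="hdf5"))
    by_key: dict = {}
    for s in sessions:
        by_key.setdefault((s.horse_id, s.gait.value), {})[s.run.value] = s
    pairs = []
    for (horse, gait), runs in sorted(by_key.items()):
        if "before" in runs and "after" in runs:
            pairs.append((runs["before"], runs["after"]))
        else:
            logger.warning("horse %s gait %s: missing run, skipped", horse, gait)
    if not pairs:
        raise PipelineError(f"stage load: no before/after pairs found in {root}")
    return pairs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Returns ``{"records", "results", "tables", "qc"}`` in memory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_records = []
    all_qc = []

    if config.mode == "synthetic":
        effect = FatigueEffect(shape_delta=config.shape_delta,
                               amp_delta=config.amp_delta,
                               roughness_delta=config.roughness_delta)
        spec = _herd_spec(config)
        for gait in config.gaits:
            template = default_template(Gait(gait))
            with _stage("synthesis", gait):
                pairs = generate_herd(spec, template, effect)
            for before, after in pairs:
                all_records.extend(pair_indicators(before, after, config, all_qc))
    elif config.mode == "directory":
        for before, after in _load_pairs(config):
            all_records.extend(pair_indicators(before, after, config, all_qc))
    else:
        raise ValidationError(f"unknown pipeline mode {config.mode!r}")

    logger.info("indicator records: %d", len(all_records))
    egio.write_indicator_table(all_records, out / "indicators.csv")
    pd.DataFrame(all_qc).to_csv(out / "qc.csv", index=False)

    with _stage("screening"):
        results = screen_indicators(all_records, alpha=config.alpha,
                                    pool_sides=config.pool_sides, bh=config.bh)
        from .stats import apply_cc_retention
        apply_cc_retention(results, threshold=config.cc_retention)
        tables = report_tables(results)

    screen_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    screen_df.to_csv(out / "screen_all.csv", index=False)
    for name in ("CC", "RMSD", "SPARC"):
        tables[name].to_csv(out / f"screen_{name.lower()}.csv", index=False)
    tables["sensor_counts"].to_csv(out / "sensor_counts.csv", index=False)

    import scipy

    from . import __version__

    manifest = {"config": config.to_dict(),
                "versions": {"equigait": __version__,
                             "numpy": np.__version__,
                             "scipy": scipy.__version__},
                "n_records": len(all_records),
                "n_keys": len(results),
                "n_significant": int(sum(r.significant for r in results)),
                "n_retained": int(sum(r.retained for r in results))}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    logger.info("screened %d keys: %d significant, %d retained",
                manifest["n_keys"], manifest["n_significant"], manifest["n_retained"])
    return {"records": all_records, "results": results, "tables": tables,
            "qc": all_qc}
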