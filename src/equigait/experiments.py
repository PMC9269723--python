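"""Seeded simulation experiments on the synthetic herd.

These experiments characterize the pipeline end-to-end on generated
data: segmentation recovery against the generator's ground truth,
type-I calibration of the indicator screen under the null (all fatigue
knobs zero), and power/direction of the CC screen under a waveform-shape
effect.  The screening experiments run on a reduced sensor set (sternum
+ left forelimb cannon, one gait) with the full herd design otherwise
(10 horses, 2 passages per run, 10 s passages); the reduction keeps
replicated experiments fast without touching the study conditions that
matter to the statistics.
"""

from __future__ import annotations

import numpy as np

from .datamodel import Gait, Run
from .kinematics import derive_channels
from .pipeline import PipelineConfig, pair_indicators
from .segmentation import FLAG_EDGE, detect_strides, lowpass_butterworth
from .stats import screen_indicators
from .synthetic import FatigueEffect, HerdSpec, default_template, generate_herd, generate_session

#: sensor subset used by the replicated screening experiments
SCREEN_SENSORS = ("ST", "FC_L")

__all__ = [
    "screening_replicate",
    "null_calibration",
    "shape_power",
    "segmentation_recovery",
]


def screening_replicate(seed: int, effect: FatigueEffect,
                        gait=Gait.CANTER, sensors=SCREEN_SENSORS,
                        n_horses: int = 10, passages_per_run: int = 2,
                        duration_s: float = 10.0) -> list:
    """Generate one herd, run the full pipeline, screen the indicators."""
    template = default_template(gait).subset(sensors)
    spec = HerdSpec(n_horses=n_horses, passages_per_run=passages_per_run,
                    duration_s=duration_s, seed=seed)
    cfg = PipelineConfig(n_horses=n_horses, passages_per_run=passages_per_run,
                         duration_s=duration_s, seed=seed)
    records = []
    for before, after in generate_herd(spec, template, effect):
        records.extend(pair_indicators(before, after, cfg))
    return screen_indicators(records)


def null_calibration(n_seeds: int = 200, base_seed: int = 0, **kwargs) -> dict:
    """Empirical rejection rate of the screen with all fatigue knobs zero.

    Pools every screened key over ``n_seeds`` independent herds and
    reports the overall fraction rejected at alpha = 0.05, plus the
    per-seed rejection rate of the stride-duration key alone.
    """
    n_sig = n_tot = 0
    dur_sig = dur_tot = 0
    for i in range(n_seeds):
        results = screening_replicate(base_seed + i, FatigueEffect.null(), **kwargs)
        for r in results:
            n_tot += 1
            n_sig += r.significant
            if r.indicator == "stride_duration":
                dur_tot += 1
                dur_sig += r.significant
    return {
        "rejection_rate": n_sig / n_tot,
        "duration_rejection_rate": dur_sig / dur_tot,
        "n_tests": n_tot,
        "n_seeds": n_seeds,
    }


def shape_power(n_seeds: int = 50, base_seed: int = 0, shape_delta: float = 0.3,
                sensor: str = "ST", channels=("acc_z", "acc_vert"),
                **kwargs) -> dict:
    """Detection rate of a waveform-shape effect on sternum CC indicators.

    A seed counts as a detection when every checked channel's CC key is
    significant with the intra-run CC exceeding the inter-run CC
    (direction "decrease": the after-run strides resemble the
    before-run reference less than the before-run strides do).
    """
    effect = FatigueEffect(shape_delta=shape_delta)
    hits = 0
    for i in range(n_seeds):
        results = screening_replicate(base_seed + i, effect, **kwargs)
        keyed = {(r.sensor, r.channel): r for r in results if r.indicator == "CC"}
        ok = all(
            (sensor, ch) in keyed
            and keyed[(sensor, ch)].significant
            and keyed[(sensor, ch)].direction == "decrease"
            for ch in channels
        )
        hits += ok
    return {"power": hits / n_seeds, "n_seeds": n_seeds, "shape_delta": shape_delta}


def segmentation_recovery(n_passages: int = 50, base_seed: int = 0,
                          gait=Gait.CANTER, noise_sd: float = 0.5,
                          timing_jitter: float = 0.02,
                          duration_s: float = 10.0) -> dict:
    """Stride-peak recall/precision against the generator's ground truth.

    One sternum-only passage per seed; peaks are matched to the
    generator's stride onsets within a quarter period.  Truth onsets
    closer than 0.75 period to a record edge are left out of the recall
    denominator (the detector flags and excludes edge peaks by design);
    edge-flagged detections are likewise excluded from precision.
    """
    template = default_template(gait).subset(("ST",))
    period = 1.0 / template.stride_freq
    n_matched_truth = n_truth = 0
    n_correct_det = n_det = 0
    max_err = 0.0
    for i in range(n_passages):
        spec = HerdSpec(n_horses=2, passages_per_run=1, duration_s=duration_s,
                        noise_sd_acc=noise_sd, timing_jitter=timing_jitter,
                        seed=base_seed + i)
        session = generate_session(template, FatigueEffect.null(), spec, 0, Run.BEFORE)
        rec = session.passages[0]["ST"]
        truth = np.asarray(session.truth["stride_onsets"][0])
        acc_vert = derive_channels(rec)["acc_vert"]
        b = detect_strides(lowpass_butterworth(acc_vert, rec.fs), rec.fs)
        det = np.array([t for t, f in zip(b.peak_times, b.flags) if f != FLAG_EDGE])
        interior = truth[(truth >= 0.75 * period) & (truth <= duration_s - 0.75 * period)]
        n_truth += len(interior)
        for t in interior:
            err = float(np.abs(det - t).min()) if len(det) else np.inf
            if err < 0.25 * period:
                n_matched_truth += 1
                max_err = max(max_err, err)
        n_det += len(det)
        for t in det:
            if len(truth) and np.abs(truth - t).min() < 0.25 * period:
                n_correct_det += 1
    return {
        "recall": n_matched_truth / n_truth if n_truth else float("nan"),
        "precision": n_correct_det / n_det if n_det else float("nan"),
        "max_peak_time_error_s": max_err,
        "n_passages": n_passages,
    }
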