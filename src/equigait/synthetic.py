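"""Seeded synthetic multi-sensor gait generator.

The generator emulates the measurement setting downstream stages are
built for: a herd of horses, each recorded at trot or canter in short
corridor passages before and after a training session, with nine
body-mounted IMUs.  Signals are quasi-periodic harmonic series of the
stride frequency with sensor-location-specific amplitudes and phases,
stride-to-stride timing jitter, additive sensor noise, and physically
consistent orientation/acceleration: the sensor-frame specific force is
the inverse-rotated sum of the generating global acceleration and
gravity, so resolving it back to the global frame and removing gravity
recovers the stored ground truth exactly when noise is zero.

A configurable "fatigue" effect perturbs after-runs only, with one knob
per indicator family:

* ``shape_delta`` — phase shifts of harmonics h >= 2 (waveform shape
  change; lowers inter-run CC).  Harmonic 1 is left untouched so the
  peak-based stride segmentation anchor is unaffected.
* ``amp_delta`` — multiplicative amplitude scaling (raises inter-run
  RMSD without touching CC).
* ``roughness_delta`` — band-limited 8-12 Hz content added to the
  generating accelerations and attitude oscillations (degrades
  SPARC/LDLJ smoothness).

Per-horse trait variation (amplitude factor, small phase offsets) is
drawn from the seed and horse index only, so a horse keeps its
idiosyncratic waveform across runs and the before/after pairing is
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .datamodel import (
    GRAVITY,
    Gait,
    Run,
    SensorLocation,
    SensorRecording,
    Session,
    STANDARD_LOCATIONS,
    ValidationError,
)

__all__ = [
    "GaitTemplate",
    "LocationWaveform",
    "FatigueEffect",
    "HerdSpec",
    "default_template",
    "generate_session",
    "generate_herd",
]

#: default stride frequencies (Hz): typical equine values
DEFAULT_STRIDE_FREQ = {Gait.TROT: 1.4, Gait.CANTER: 1.8}

#: harmonic amplitude decay ratio between successive harmonics
_HARMONIC_DECAY = 0.35

#: roughness noise band (Hz)
_ROUGHNESS_BAND = (8.0, 12.0)


@dataclass(frozen=True)
class LocationWaveform:
    """Harmonic coefficients for one sensor location.

    ``acc_amp``/``acc_phase`` — (H, 3) global-frame acceleration
    harmonics (m/s^2, rad).  ``eul_amp``/``eul_phase`` — (H, 3)
    attitude-oscillation harmonics about the mean attitude (rad), as
    intrinsic x-y-z rotations in the mean sensor frame.
    ``mean_attitude`` — scalar-first quaternion, sensor-to-global.
    """

    acc_amp: np.ndarray
    acc_phase: np.ndarray
    eul_amp: np.ndarray
    eul_phase: np.ndarray
    mean_attitude: np.ndarray

    def __post_init__(self):
        for name in ("acc_amp", "acc_phase", "eul_amp", "eul_phase"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "mean_attitude",
                           np.asarray(self.mean_attitude, dtype=float))
        if not np.all(np.isfinite(self.acc_amp)):
            raise ValidationError("waveform amplitudes must be finite")


@dataclass(frozen=True)
class GaitTemplate:
    """Per-gait harmonic stride templates for every sensor location."""

    gait: Gait
    stride_freq: float
    waveforms: dict
    n_harmonics: int = 5

    def __post_init__(self):
        object.__setattr__(self, "gait", Gait(self.gait))
        if not self.stride_freq > 0:
            raise ValidationError("stride_freq must be > 0")
        if self.n_harmonics < 3:
            raise ValidationError("need at least 3 harmonics")

    def subset(self, keys) -> "GaitTemplate":
        """Template restricted to a subset of sensor locations."""
        return GaitTemplate(
            gait=self.gait, stride_freq=self.stride_freq,
            waveforms={k: self.waveforms[k] for k in keys},
            n_harmonics=self.n_harmonics,
        )


@dataclass(frozen=True)
class FatigueEffect:
    """Controlled training-session perturbation (applied to after-runs)."""

    shape_delta: float = 0.0
    amp_delta: float = 0.0
    roughness_delta: float = 0.0

    def __post_init__(self):
        for name in ("shape_delta", "amp_delta", "roughness_delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

    @property
    def is_null(self) -> bool:
        return self.shape_delta == self.amp_delta == self.roughness_delta == 0.0

    @classmethod
    def null(cls) -> "FatigueEffect":
        return cls()


@dataclass(frozen=True)
class HerdSpec:
    """Study-design parameters of a synthetic herd.

    Defaults mirror the measurement design the pipeline targets: 10
    horses, 2 corridor passages per gait per run, 10 s per passage at
    128 Hz, 2% stride-timing jitter, sensor noise 0.5 m/s^2 / 0.05
    rad/s.  ``stride_amp_sd`` and ``stride_shape_sd`` set the
    stride-to-stride motor variability (relative amplitude SD and
    per-harmonic phase SD in radians): without it every stride of a
    horse would repeat to within sensor noise, which no real gait does.
    """

    n_horses: int = 10
    passages_per_run: int = 2
    duration_s: float = 10.0
    fs: float = 128.0
    noise_sd_acc: float = 0.5
    noise_sd_gyro: float = 0.05
    timing_jitter: float = 0.02
    stride_amp_sd: float = 0.05
    stride_shape_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_horses < 2:
            raise ValidationError("need at least 2 horses")
        if self.passages_per_run < 1:
            raise ValidationError("need at least 1 passage per run")


# ---------------------------------------------------------------------------
# default template


def _harmonics(amp1_xyz, H, phase_rng, zero_phase_axis=None):
    h = np.arange(1, H + 1)[:, None]
    amp = np.asarray(amp1_xyz)[None, :] * _HARMONIC_DECAY ** (h - 1)
    phase = phase_rng.uniform(-np.pi, np.pi, size=(H, 3))
    if zero_phase_axis is not None:
        phase[:, zero_phase_axis] = 0.0
    return amp, phase

# per-leg timing offsets in stride fractions (diagonal pairs at trot; the
# footfall sequence of a right-lead canter otherwise)
_LEG_PHASE = {
    Gait.TROT: {"FC_L": 0.0, "HC_R": 0.0, "FC_R": 0.5, "HC_L": 0.5},
    Gait.CANTER: {"HC_L": 0.0, "HC_R": 0.25, "FC_L": 0.25, "FC_R": 0.55},
}

# (acc amp1 x,y,z in m/s^2, euler-osc amp1 x,y,z in degrees)
_LOCATION_BASE = {
    "FH": ((1.0, 0.6, 2.0), (5.0, 6.0, 4.0)),
    "PO": ((1.0, 0.7, 2.2), (5.0, 6.0, 4.0)),
    "WI": ((1.2, 0.8, 2.5), (4.0, 5.0, 3.0)),
    "ST": ((1.5, 0.8, 3.0), (4.0, 5.0, 3.0)),
    "SA": ((1.5, 1.0, 3.5), (5.0, 6.0, 4.0)),
    "FC": ((3.0, 1.5, 5.0), (8.0, 35.0, 5.0)),
    "HC": ((3.0, 1.5, 5.0), (8.0, 35.0, 5.0)),
}

# mean attitudes: trunk/head sensors roughly x-forward, z-up; cannon
# sensors x down the limb (rotated -90 deg about y: sensor x -> global -z)
_MEAN_ATTITUDE = {
    False: np.array([1.0, 0.0, 0.0, 0.0]),
    True: np.array([np.cos(-np.pi / 4), 0.0, np.sin(-np.pi / 4), 0.0]),
}


def default_template(gait, stride_freq: float | None = None,
                     n_harmonics: int = 5) -> GaitTemplate:
    """Built-in waveform template for a gait (deterministic)."""
    gait = Gait(gait)
    if stride_freq is None:
        stride_freq = DEFAULT_STRIDE_FREQ[gait]
    waveforms = {}
    for i, loc in enumerate(STANDARD_LOCATIONS):
        # fixed per-location phase draws -> the default template is a constant
        rng = np.random.default_rng(90_000 + 97 * i + (0 if gait is Gait.TROT else 1))
        acc1, eul1 = _LOCATION_BASE[loc.code.value]
        # sternum vertical harmonics get zero phase: filtered-signal peaks
        # then coincide with stride onsets (the segmentation ground truth)
        acc_amp, acc_phase = _harmonics(
            acc1, n_harmonics, rng, zero_phase_axis=2 if loc.code.value == "ST" else None
        )
        eul_amp, eul_phase = _harmonics(np.radians(eul1), n_harmonics, rng)
        leg_off = _LEG_PHASE[gait].get(loc.key)
        if leg_off is not None:
            # a pure time shift: phase offset proportional to harmonic order
            h = np.arange(1, n_harmonics + 1)[:, None]
            acc_phase = acc_phase + 2 * np.pi * leg_off * h
            eul_phase = eul_phase + 2 * np.pi * leg_off * h
        if gait is Gait.CANTER and not loc.is_cannon:
            # canter pitch: stronger harmonic-1 rotation about lateral axis
            eul_amp = eul_amp.copy()
            eul_amp[0, 1] += np.radians(4.0)
        waveforms[loc.key] = LocationWaveform(
            acc_amp=acc_amp, acc_phase=acc_phase,
            eul_amp=eul_amp, eul_phase=eul_phase,
            mean_attitude=_MEAN_ATTITUDE[loc.is_cannon],
        )
    return GaitTemplate(gait=gait, stride_freq=stride_freq,
                        waveforms=waveforms, n_harmonics=n_harmonics)


# ---------------------------------------------------------------------------
# generation helpers


def _bandlimited_noise(rng, n, fs, sd):
    """Zero-mean noise confined to the roughness band, rescaled to sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < _ROUGHNESS_BAND[0]) | (f > _ROUGHNESS_BAND[1])] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _stride_phase(rng, duration, fs, stride_freq, jitter):
    """Piecewise-linear stride phase and the onset times (phase = integer)."""
    period = 1.0 / stride_freq
    t0 = rng.uniform(0.0, period)
    n_strides = int(np.ceil((duration + 2 * period) / period)) + 2
    factors = 1.0 + jitter * np.clip(rng.standard_normal(n_strides), -3, 3)
    onsets = t0 - period * factors[0] + np.concatenate([[0.0], np.cumsum(period * factors)])
    t = np.arange(int(round(duration * fs))) / fs
    phase = np.interp(t, onsets, np.arange(len(onsets), dtype=float))
    in_range = (onsets >= 0.0) & (onsets < duration)
    return t, phase, onsets[in_range], onsets


def _horse_traits(seed, horse_index, template):
    """Per-horse waveform idiosyncrasy, fixed across runs/passages."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(1, int(horse_index)))
    )
    amp_factor = float(np.exp(0.10 * rng.standard_normal()))
    phase_offsets = {
        key: rng.normal(0.0, 0.06, size=wf.acc_phase.shape)
        for key, wf in sorted(template.waveforms.items())
    }
    return amp_factor, phase_offsets


def _harmonic_series(phase, amp, ph, extra_phase=None):
    """sum_h amp[h, ax] * cos(2*pi*h*phase + ph[h, ax] (+ extra)) -> (T, 3).

    ``extra_phase`` is an optional (T, H) time-varying phase term shared
    across axes (stride-to-stride waveform variability).
    """
    H = amp.shape[0]
    h = np.arange(1, H + 1)
    args = 2 * np.pi * phase[:, None, None] * h[None, :, None] + ph[None, :, :]
    if extra_phase is not None:
        args = args + extra_phase[:, :, None]
    return np.einsum("thx,hx->tx", np.cos(args), amp)


def _body_rates(rotations, fs):
    """Sensor-frame angular velocity from an orientation trajectory.

    Central finite differences of the relative rotation (one-sided at the
    edges); adequate for smooth synthetic trajectories.
    """
    n = len(rotations)
    omega = np.empty((n, 3))
    rel = (rotations[:-2].inv() * rotations[2:]).as_rotvec() * (fs / 2.0)
    omega[1:-1] = rel
    omega[0] = (rotations[0].inv() * rotations[1]).as_rotvec() * fs
    omega[-1] = (rotations[-2].inv() * rotations[-1]).as_rotvec() * fs
    return omega


def generate_session(template: GaitTemplate, effect: FatigueEffect,
                     spec: HerdSpec, horse_index: int, run) -> Session:
    """Generate one (horse, gait, run) session with ground-truth sidecar.

    The fatigue effect is applied only when ``run`` is ``after``.
    Determinism: output depends only on (template, effect, spec fields,
    horse_index, run).
    """
    run = Run(run)
    if spec.duration_s * template.stride_freq < 2:
        raise ValidationError(
            f"duration {spec.duration_s}s too short for 2 strides at "
            f"{template.stride_freq} Hz"
        )
    apply_effect = run is Run.AFTER
    amp_factor, phase_offsets = _horse_traits(spec.seed, horse_index, template)
    H = template.n_harmonics
    h_idx = np.arange(1, H + 1)[:, None]
    shape_shift = np.where(h_idx >= 2, 2.0 * effect.shape_delta * h_idx, 0.0)
    amp_scale = 1.0 + (effect.amp_delta if apply_effect else 0.0)

    passages = []
    truth_onsets = []
    truth_acc = []
    for p in range(spec.passages_per_run):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=int(spec.seed),
            spawn_key=(2, int(horse_index), 0 if run is Run.BEFORE else 1, p),
        ))
        t, phase, onsets, knots = _stride_phase(
            rng, spec.duration_s, spec.fs, template.stride_freq, spec.timing_jitter
        )
        passage = {}
        passage_truth = {}
        for key in sorted(template.waveforms):
            wf = template.waveforms[key]
            loc = SensorLocation.from_key(key)
            acc_phase = wf.acc_phase + phase_offsets[key]
            eul_phase = wf.eul_phase + phase_offsets[key]
            if apply_effect:
                acc_phase = acc_phase + shape_shift
                eul_phase = eul_phase + shape_shift
            # stride-to-stride motor variability: smooth per-stride
            # amplitude modulation and per-harmonic waveform phase noise
            amp_mod = None
            phase_mod = None
            if spec.stride_amp_sd > 0:
                nodes = rng.normal(0.0, spec.stride_amp_sd, len(knots))
                amp_mod = 1.0 + np.interp(t, knots, nodes)
            if spec.stride_shape_sd > 0:
                nodes = rng.normal(0.0, spec.stride_shape_sd, (len(knots), H))
                phase_mod = np.stack(
                    [np.interp(t, knots, nodes[:, j]) for j in range(H)], axis=1)
            a_global = amp_factor * amp_scale * _harmonic_series(
                phase, wf.acc_amp, acc_phase, phase_mod)
            eul = amp_factor * _harmonic_series(phase, wf.eul_amp, eul_phase, phase_mod)
            if amp_mod is not None:
                a_global = a_global * amp_mod[:, None]
                eul = eul * amp_mod[:, None]
            if apply_effect and effect.roughness_delta > 0:
                for ax in range(3):
                    a_global[:, ax] += _bandlimited_noise(
                        rng, len(t), spec.fs,
                        effect.roughness_delta * a_global[:, ax].std())
                    eul[:, ax] += _bandlimited_noise(
                        rng, len(t), spec.fs,
                        effect.roughness_delta * eul[:, ax].std())
            r_mean = Rotation.from_quat(wf.mean_attitude, scalar_first=True)
            r_osc = Rotation.from_euler("xyz", eul)
            rot = r_mean * r_osc
            quat = rot.as_quat(scalar_first=True)
            quat *= np.where(quat[:, :1] < 0, -1.0, 1.0)
            gyro = _body_rates(rot, spec.fs)
            specific_force = a_global.copy()
            specific_force[:, 2] += GRAVITY
            acc_sensor = rot.inv().apply(specific_force)
            if spec.noise_sd_acc > 0:
                acc_sensor = acc_sensor + rng.normal(0, spec.noise_sd_acc, acc_sensor.shape)
            if spec.noise_sd_gyro > 0:
                gyro = gyro + rng.normal(0, spec.noise_sd_gyro, gyro.shape)
            passage[key] = SensorRecording(
                location=loc, fs=spec.fs, acc=acc_sensor, gyro=gyro, quat=quat
            )
            passage_truth[key] = a_global
        passages.append(passage)
        truth_onsets.append(onsets)
        truth_acc.append(passage_truth)

    return Session(
        horse_id=f"H{horse_index + 1:02d}",
        gait=template.gait,
        run=run,
        passages=passages,
        truth={
            "stride_onsets": truth_onsets,
            "a_global": truth_acc,
            "stride_freq": template.stride_freq,
        },
    )


def generate_herd(spec: HerdSpec, template: GaitTemplate,
                  effect: FatigueEffect) -> list:
    """Before/after session pairs for every horse in the herd.

    Before-runs are always effect-free; the fatigue effect perturbs
    after-runs only.  Each horse draws from an independent seeded
    substream.
    """
    pairs = []
    for horse in range(spec.n_horses):
        before = generate_session(template, FatigueEffect.null(), spec, horse, Run.BEFORE)
        after = generate_session(template, effect, spec, horse, Run.AFTER)
        pairs.append((before, after))
    return pairs
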