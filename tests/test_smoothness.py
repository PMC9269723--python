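import numpy as np
import pytest

import equigait as eg
from equigait.datamodel import SensorLocation, SensorRecording
from equigait.segmentation import detect_strides, lowpass_butterworth
from equigait.smoothness import (
    DegenerateSignalError,
    SparcParams,
    ldlj_a,
    sparc,
    sparc_batch,
    sparc_gyro_norm,
    spectrum_grid,
)
from equigait.kinematics import derive_channels
from helpers import arc_length_oracle, dtft_magnitudes

FS = 128.0


class TestSparc:
    def test_scale_invariance(self):
        v = np.random.default_rng(0).standard_normal(200)
        assert abs(sparc(v, FS) - sparc(5.0 * v, FS)) < 1e-9

    def test_never_above_minus_one(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(8, 400)
            assert sparc(rng.standard_normal(n), FS) <= -1.0 + 1e-12

    def test_two_tone_is_less_smooth_and_matches_arc_oracle(self):
        """A second tone lengthens the normalized spectrum's arc; both
        values must agree with an independent numerical integration of
        the arc-length functional on a 10x finer grid."""
        t = np.arange(0, 10.0, 1 / FS)
        one = np.sin(2 * np.pi * 2.0 * t)
        two = one + 0.5 * np.sin(2 * np.pi * 6.0 * t)
        s_one, s_two = sparc(one, FS), sparc(two, FS)
        assert s_two < s_one
        params = SparcParams()
        for v, s in ((one, s_one), (two, s_two)):
            fk, mk = spectrum_grid(v, FS, params)
            assert abs(-arc_length_oracle(fk, mk, params.fc, refine=10) - s) < 1e-6

    def test_spectrum_matches_brute_force_dtft(self):
        """The padded-FFT spectrum samples equal a direct DTFT evaluation."""
        v = np.random.default_rng(3).standard_normal(64)
        fk, mk = spectrum_grid(v, FS, SparcParams())
        nfft = 256  # next power of two >= 4x segment length
        full = np.fft.rfftfreq(nfft, 1 / FS)
        oracle = dtft_magnitudes(v, fk[:-1], FS)  # last point is interpolated
        oracle = oracle / dtft_magnitudes(v, full, FS).max()
        assert np.abs(mk[:-1] - oracle).max() < 1e-9

    def test_constant_signal_is_perfectly_smooth(self):
        assert sparc(np.full(100, 3.3), FS) == -1.0

    def test_all_zero_signal_rejected(self):
        with pytest.raises(DegenerateSignalError, match="degenerate spectrum"):
            sparc(np.zeros(100), FS)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(4)
        seg = rng.standard_normal((75, 5))
        seg[:, 2] = 1.0  # constant column
        vals = sparc_batch(seg, FS)
        for i in range(5):
            assert abs(vals[i] - sparc(seg[:, i], FS)) < 1e-12

    def test_sample_offset_invariance(self):
        v = np.random.default_rng(6).standard_normal(300)
        assert sparc(v[10:110], FS) == sparc(np.roll(v, -10)[:100], FS)


def _spin_recording(gyro, fs=FS):
    T = len(gyro)
    return SensorRecording(location=SensorLocation.from_key("FC_L"), fs=fs,
                           acc=np.tile([0, 0, 9.81], (T, 1)), gyro=gyro,
                           quat=np.tile([1.0, 0, 0, 0], (T, 1)))


class TestSparcGyroNorm:
    def _boundaries(self, n, fs):
        t = np.arange(n) / fs
        return detect_strides(np.sin(2 * np.pi * 2.0 * t), fs)

    def test_constant_rate_rotation_is_perfectly_smooth(self):
        T = int(5 * FS)
        rec = _spin_recording(np.tile([0.0, 0.0, 2.0], (T, 1)))
        vals = sparc_gyro_norm(rec, self._boundaries(T, FS))
        assert np.allclose(vals, -1.0)

    def test_invariant_under_fixed_mounting_rotation(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        T = int(5 * FS)
        gyro = rng.standard_normal((T, 3))
        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        b = self._boundaries(T, FS)
        v0 = sparc_gyro_norm(_spin_recording(gyro), b)
        v1 = sparc_gyro_norm(_spin_recording(gyro @ R.as_matrix().T), b)
        assert np.abs(v0 - v1).max() < 1e-9

    def test_roughness_degrades_smoothness(self, canter_template):
        tpl = canter_template.subset(("ST",))
        means = []
        for rough in (0.0, 0.5):
            spec = eg.HerdSpec(n_horses=2, passages_per_run=1, duration_s=8.0,
                               seed=13)
            s = eg.generate_session(tpl, eg.FatigueEffect(roughness_delta=rough),
                                    spec, 0, "after")
            rec = s.passages[0]["ST"]
            acc_vert = derive_channels(rec)["acc_vert"]
            b = detect_strides(lowpass_butterworth(acc_vert, rec.fs), rec.fs)
            means.append(sparc_gyro_norm(rec, b).mean())
        assert means[1] < means[0]


class TestLdlj:
    @pytest.mark.parametrize("freq_hz,T", [(1.0, 2.0), (0.5, 4.0), (2.0, 3.0)])
    def test_sinusoid_matches_closed_form(self, freq_hz, T):
        """For a_g = sin(w t) x-hat over whole periods the dimensionless
        jerk integral reduces to w^2 T^2 / 2."""
        fs = 1000.0
        w = 2 * np.pi * freq_hz
        t = np.arange(0, T, 1 / fs)
        acc = np.zeros((len(t), 3))
        acc[:, 0] = np.sin(w * t)
        acc[:, 2] += 9.81  # identity attitude: gravity along sensor z
        quat = np.tile([1.0, 0, 0, 0], (len(t), 1))
        expected = -np.log(w**2 * T**2 / 2.0)
        got = ldlj_a(acc, quat, fs, (0.0, T))
        assert abs(got - expected) / abs(expected) < 1e-3

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(8)
        fs = 200.0
        a_g = rng.standard_normal((400, 3))
        quat = np.tile([1.0, 0, 0, 0], (400, 1))
        def with_gravity(a):
            out = a.copy()
            out[:, 2] += 9.81
            return out
        v0 = ldlj_a(with_gravity(a_g), quat, fs, (0.0, 2.0))
        v1 = ldlj_a(with_gravity(7.0 * a_g), quat, fs, (0.0, 2.0))
        assert abs(v0 - v1) < 1e-9

    def test_constant_acceleration_degenerate(self):
        quat = np.tile([1.0, 0, 0, 0], (400, 1))
        acc = np.tile([1.0, 0.0, 9.81], (400, 1))
        with pytest.raises(DegenerateSignalError, match="constant acceleration"):
            ldlj_a(acc, quat, 100.0, (0.0, 2.0))

    def test_roughness_degrades_ldlj(self, canter_template):
        from equigait.smoothness import ldlj_per_stride

        tpl = canter_template.subset(("ST",))
        means = []
        for rough in (0.0, 0.5):
            spec = eg.HerdSpec(n_horses=2, passages_per_run=1, duration_s=8.0,
                               seed=14)
            s = eg.generate_session(tpl, eg.FatigueEffect(roughness_delta=rough),
                                    spec, 0, "after")
            rec = s.passages[0]["ST"]
            acc_vert = derive_channels(rec)["acc_vert"]
            b = detect_strides(lowpass_butterworth(acc_vert, rec.fs), rec.fs)
            means.append(ldlj_per_stride(rec, b).mean())
        assert means[1] < means[0]
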