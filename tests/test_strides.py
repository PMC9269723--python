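import numpy as np
import pytest

from equigait.datamodel import ValidationError
from equigait.strides import (
    NormalizedStrideGroup,
    build_group,
    compare,
    compare_rows,
    normalize_stride,
    run_indicators,
)
from helpers import pchip_oracle


class TestNormalizeStride:
    def test_output_length_is_100(self):
        rng = np.random.default_rng(0)
        for n in (4, 17, 64, 211):
            assert len(normalize_stride(rng.standard_normal(n))) == 100

    def test_constant_preserved(self):
        out = normalize_stride(np.full(37, 2.5))
        assert np.allclose(out, 2.5, atol=1e-12)

    def test_linear_ramp_reproduced_exactly(self):
        for n in (5, 23, 81):
            out = normalize_stride(np.linspace(-1.0, 3.0, n))
            assert np.abs(out - np.linspace(-1.0, 3.0, 100)).max() < 1e-12

    def test_endpoints_preserved(self):
        y = np.random.default_rng(2).standard_normal(41)
        out = normalize_stride(y)
        assert abs(out[0] - y[0]) < 1e-12 and abs(out[-1] - y[-1]) < 1e-12

    def test_matches_fritsch_carlson_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.standard_normal(37).cumsum()
            assert np.abs(normalize_stride(y) - pchip_oracle(y)).max() < 1e-10

    def test_too_short_stride_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            normalize_stride(np.arange(3.0))


class TestBuildGroup:
    def test_tie_breaks_to_lowest_index(self):
        row = np.sin(np.linspace(0, 2 * np.pi, 100))
        g = build_group(np.tile(row, (3, 1)))
        assert g.ref_index == 0

    def test_outlier_never_chosen_as_reference(self):
        row = np.sin(np.linspace(0, 2 * np.pi, 100))
        strides = np.vstack([np.tile(row, (4, 1)), row + 5.0])
        assert build_group(strides).ref_index in (0, 1, 2, 3)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            strides = rng.standard_normal((8, 100))
            g = build_group(strides)
            mean = strides.mean(axis=0)
            rmsds = [np.sqrt(np.mean((row - mean) ** 2)) for row in strides]
            assert g.ref_index == int(np.argmin(rmsds))
            # defining property: reference is no farther from the mean
            assert rmsds[g.ref_index] <= min(rmsds) + 1e-15

    def test_single_stride_rejected(self):
        with pytest.raises(ValidationError):
            build_group(np.ones((1, 100)))


class TestCompare:
    def test_self_comparison(self):
        s = np.random.default_rng(1).standard_normal(100)
        cc, rmsd = compare(s, s)
        assert cc == 1.0 and rmsd == 0.0

    def test_offset_hits_rmsd_only(self):
        s = np.random.default_rng(2).standard_normal(100)
        cc, rmsd = compare(s, s + 2.0)
        assert abs(cc - 1.0) < 1e-12
        assert abs(rmsd - 2.0) < 1e-12

    def test_antisymmetric_pair(self):
        s = np.sin(np.linspace(0, 4 * np.pi, 100))
        s = s - s.mean()
        cc, rmsd = compare(s, -s)
        assert abs(cc + 1.0) < 1e-12
        assert abs(rmsd - 2 * np.sqrt(np.mean(s**2))) < 1e-12

    def test_zero_variance_gives_nan_cc_finite_rmsd(self):
        cc, rmsd = compare(np.full(100, 1.0), np.linspace(0, 1, 100))
        assert np.isnan(cc) and np.isfinite(rmsd)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((2, 100))
        assert compare(a, b) == compare(b, a)

    def test_scale_invariance_and_equivariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 100))
        cc0, rmsd0 = compare(a, b)
        cc1, rmsd1 = compare(-3.0 * a, -3.0 * b)
        assert abs(cc0 - cc1) < 1e-12
        assert abs(rmsd1 - 3.0 * rmsd0) < 1e-12

    def test_rows_variant_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        rows = rng.standard_normal((7, 100))
        ref = rng.standard_normal(100)
        ccs, rmsds = compare_rows(rows, ref)
        for i, row in enumerate(rows):
            cc, rmsd = compare(row, ref)
            assert abs(cc - ccs[i]) < 1e-12 and abs(rmsd - rmsds[i]) < 1e-12


def _group(strides, run):
    return NormalizedStrideGroup(horse="H01", gait="canter", run=run,
                                 sensor="ST", side="midline", channel="acc_z",
                                 strides=strides)


class TestRunIndicators:
    def test_identical_groups_are_null(self):
        row = np.sin(np.linspace(0, 2 * np.pi, 100))
        strides = np.tile(row, (5, 1))
        recs = run_indicators(_group(strides, "before"), _group(strides.copy(), "after"))
        vals = {(r.indicator, r.scope): r.value for r in recs}
        assert vals[("CC", "inter")] == vals[("CC", "intra_before")] == 1.0
        assert vals[("RMSD", "inter")] == vals[("RMSD", "intra_before")] == 0.0

    def test_offset_effect_hits_rmsd_not_cc(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 100))
        strides = np.tile(base, (6, 1))
        recs = run_indicators(_group(strides, "before"),
                              _group(strides + 1.5, "after"))
        vals = {(r.indicator, r.scope): r.value for r in recs}
        assert vals[("CC", "inter")] == vals[("CC", "intra_before")] == 1.0
        assert vals[("RMSD", "inter")] == 1.5 > vals[("RMSD", "intra_before")]

    def test_emits_all_scopes(self):
        rng = np.random.default_rng(10)
        recs = run_indicators(_group(rng.standard_normal((4, 100)), "before"),
                              _group(rng.standard_normal((5, 100)), "after"))
        scopes = {(r.indicator, r.scope) for r in recs}
        for ind in ("CC", "RMSD"):
            for scope in ("intra_before", "intra_after", "inter", "inter_sym"):
                assert (ind, scope) in scopes

    def test_mismatched_groups_rejected(self):
        rng = np.random.default_rng(11)
        a = _group(rng.standard_normal((4, 100)), "before")
        b = NormalizedStrideGroup(horse="H02", gait="canter", run="after",
                                  sensor="ST", side="midline", channel="acc_z",
                                  strides=rng.standard_normal((4, 100)))
        with pytest.raises(ValidationError, match="horse"):
            run_indicators(a, b)
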