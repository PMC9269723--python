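import numpy as np
import pytest
from scipy import stats as sstats

from equigait.stats import (
    format_mean_sd,
    report_tables,
    screen_indicators,
    wilcoxon_paired,
)
from equigait.strides import IndicatorRecord
from helpers import wilcoxon_enumeration_p


class TestWilcoxonPaired:
    def test_all_positive_differences_n6(self):
        y = np.zeros(6)
        x = np.array([1.0, 2, 3, 4, 5, 6])
        res = wilcoxon_paired(x, y)
        assert res.statistic == 21.0
        assert abs(res.p_value - 2.0 / 64.0) < 1e-15
        assert res.direction == "decrease"  # y below x

    def test_identical_samples_degenerate(self):
        res = wilcoxon_paired(np.arange(10.0), np.arange(10.0))
        assert res.degenerate and res.p_value == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n in (5, 6, 8, 10, 12):
            for _ in range(20):
                x = rng.standard_normal(n)
                y = rng.standard_normal(n)
                assert abs(wilcoxon_paired(x, y).p_value
                           - wilcoxon_enumeration_p(x, y)) < 1e-12

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 4, size=9).astype(float)
            y = rng.integers(0, 4, size=9).astype(float)
            if np.all(x == y):
                continue
            assert abs(wilcoxon_paired(x, y).p_value
                       - wilcoxon_enumeration_p(x, y)) < 1e-12

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.standard_normal(11)
            y = rng.standard_normal(11)
            ours = wilcoxon_paired(x, y).p_value
            ref = sstats.wilcoxon(x, y, method="exact").pvalue
            assert abs(ours - ref) < 1e-12

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(12)
        y = x + rng.standard_normal(12) * 0.5
        a = wilcoxon_paired(x, y)
        b = wilcoxon_paired(y, x)
        assert a.p_value == b.p_value
        assert {a.direction, b.direction} in ({"increase", "decrease"}, {"none"})

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40)
        y = x + 0.8 + rng.standard_normal(40) * 0.3
        res = wilcoxon_paired(x, y)
        ref = sstats.wilcoxon(x, y, correction=True, method="approx").pvalue
        assert abs(res.p_value - ref) < 1e-6
        assert res.direction == "increase"

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError, match="insufficient pairs"):
            wilcoxon_paired([1.0, 2, 3], [0.0, 0, 0])

    def test_nan_pairs_removed(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, np.nan])
        y = np.zeros(7)
        res = wilcoxon_paired(x, y)
        assert res.n_used == 6


def _records(indicator, scope, values, channel="acc_z"):
    return [
        IndicatorRecord(horse=f"H{i:02d}", gait="canter", sensor="ST",
                        side="midline", channel=channel, indicator=indicator,
                        scope=scope, run="before", value=float(v))
        for i, v in enumerate(values)
    ]


def _cc_records(intra, inter, channel="acc_z"):
    return (_records("CC", "intra_before", intra, channel)
            + _records("CC", "inter", inter, channel))


class TestScreenIndicators:
    def test_consistent_shift_detected_with_direction(self):
        rng = np.random.default_rng(5)
        intra = 0.95 + 0.01 * rng.standard_normal(10)
        inter = intra - 0.05
        results = screen_indicators(_cc_records(intra, inter))
        (r,) = results
        assert r.significant and r.p_value < 0.01
        assert r.direction == "decrease" and r.retained

    def test_cc_retention_threshold(self):
        rng = np.random.default_rng(6)
        low = 0.75 + 0.005 * rng.standard_normal(10)
        high = 0.85 + 0.005 * rng.standard_normal(10)
        res_low = screen_indicators(_cc_records(low, low - 0.05))
        res_high = screen_indicators(_cc_records(high, high - 0.05))
        assert res_low[0].significant and not res_low[0].retained
        assert res_high[0].significant and res_high[0].retained

    def test_rmsd_retained_regardless_of_level(self):
        rng = np.random.default_rng(7)
        intra = 0.2 + 0.01 * rng.standard_normal(10)
        recs = (_records("RMSD", "intra_before", intra)
                + _records("RMSD", "inter", intra + 0.1))
        (r,) = screen_indicators(recs)
        assert r.significant and r.retained

    def test_retained_is_subset_of_significant(self):
        rng = np.random.default_rng(8)
        recs = []
        for ch in ("acc_x", "acc_y", "acc_z", "gyro_x"):
            intra = 0.82 + 0.05 * rng.standard_normal(10)
            inter = intra - rng.uniform(0, 0.04)
            recs += _cc_records(intra, inter, channel=ch)
        results = screen_indicators(recs)
        assert all(r.significant for r in results if r.retained)

    def test_side_pooling_merges_cannons(self):
        rng = np.random.default_rng(9)
        recs = []
        for side in ("left", "right"):
            for scope, shift in (("intra_before", 0.0), ("inter", -0.05)):
                recs += [
                    IndicatorRecord(horse=f"H{i:02d}", gait="canter", sensor="FC",
                                    side=side, channel="swing", indicator="CC",
                                    scope=scope, run="before",
                                    value=float(0.9 + 0.01 * rng.standard_normal() + shift))
                    for i in range(10)
                ]
        pooled = screen_indicators(recs, pool_sides=True)
        split = screen_indicators(recs, pool_sides=False)
        assert [r.sensor for r in pooled] == ["FC"]
        assert sorted(r.sensor for r in split) == ["FC_L", "FC_R"]

    def test_missing_scope_skipped(self):
        rng = np.random.default_rng(10)
        recs = _records("CC", "intra_before", 0.9 + 0.01 * rng.standard_normal(10))
        assert screen_indicators(recs) == []


class TestReporting:
    def test_mean_sd_formatting(self):
        assert format_mean_sd(0.921, 0.0449) == "0.92 (0.04)"
        assert format_mean_sd(-2.40, 0.0) == "-2.4 (0)"
        assert format_mean_sd(6.55, 3.0) == "6.55 (3)"

    def test_empty_results_give_empty_tables(self):
        tables = report_tables([])
        assert tables["CC"].empty and tables["RMSD"].empty and tables["SPARC"].empty
        assert len(tables["sensor_counts"]) == 0

    def test_counts_concentrate_on_affected_sensor(self):
        rng = np.random.default_rng(11)

        def make(sensor, scope, values, ch):
            return [IndicatorRecord(horse=f"H{i:02d}", gait="canter",
                                    sensor=sensor, side="midline", channel=ch,
                                    indicator="CC", scope=scope, run="before",
                                    value=float(v)) for i, v in enumerate(values)]

        recs = []
        for sensor, shift in (("ST", -0.05), ("SA", 0.0)):
            for ch in ("acc_x", "acc_z"):
                intra = 0.9 + 0.01 * rng.standard_normal(10)
                recs += make(sensor, "intra_before", intra, ch)
                recs += make(sensor, "inter", intra + shift, ch)
        results = screen_indicators(recs)
        tables = report_tables(results)
        counts = dict(zip(tables["sensor_counts"]["sensor"],
                          tables["sensor_counts"]["n_significant"]))
        assert counts.get("ST", 0) == 2 and counts.get("SA", 0) == 0
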