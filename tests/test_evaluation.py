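"""Band RMSE, DBS-peak detection, robustness and optimal-parameter rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from megdbs.spectral import BandPowerSummary, SpectrumEstimate
from megdbs.evaluation import (BandSet, Report, SweepResult, detect_dbs_peak,
                               make_report, rmse_band, robustness,
                               select_optimal_sensor, select_optimal_source)


def summary(pi, band=((11.5, 12.5),)):
    pi = np.asarray(pi, dtype=float)
    return BandPowerSummary(band=band, pi=pi, n_channels=pi.size)


class TestRmse:
    def test_identical_summaries_give_zero(self):
        assert rmse_band(summary([2.0, 3.0]), summary([2.0, 3.0])).value == 0.0

    def test_single_channel_hand_case(self):
        # |(3-2)/2| = 0.5
        assert rmse_band(summary([3.0]), summary([2.0])).value == pytest.approx(0.5)

    def test_two_channel_hand_case(self):
        # sqrt((0.25 + 0)/2) = 0.3535533...
        r = rmse_band(summary([3.0, 4.0]), summary([2.0, 4.0]))
        assert r.value == pytest.approx(np.sqrt(0.125), abs=1e-10)

    def test_zero_reference_power_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rmse_band(summary([1.0]), summary([0.0]))

    def test_mismatched_bands_rejected(self):
        with pytest.raises(ValueError, match="bands"):
            rmse_band(summary([1.0]), summary([1.0], band=((1.0, 2.0),)))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_invariant_to_channel_permutation(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(-30, -20, 12)
        clean = ref + rng.normal(0, 0.5, 12)
        perm = rng.permutation(12)
        assert rmse_band(summary(clean), summary(ref)).value == pytest.approx(
            rmse_band(summary(clean[perm]), summary(ref[perm])).value)


class TestPeakDetection:
    def make_spec(self, peak_freq=None, n_ch=4):
        freqs = np.arange(0, 200, 0.25)
        rng = np.random.default_rng(0)
        power = 1e-28 * (1 + 0.01 * rng.random((n_ch, freqs.size)))
        if peak_freq is not None:
            power[:, np.argmin(np.abs(freqs - peak_freq))] *= 300
        return SpectrumEstimate(freqs=freqs, power=power, window_length=4.0,
                                overlap=0.5, window_kind="hamming", n_windows=8)

    def test_finds_injected_peak(self):
        spec = self.make_spec(127.75)
        assert detect_dbs_peak(spec) == pytest.approx(127.75, abs=0.25)

    def test_no_peak_raises(self):
        with pytest.raises(ValueError, match="no DBS peak"):
            detect_dbs_peak(self.make_spec(None))

    def test_search_interval_respected(self):
        spec = self.make_spec(130.0)
        with pytest.raises(ValueError):
            detect_dbs_peak(spec, search=(300.0, 400.0))


class TestBandSet:
    def test_bands_follow_detected_peak(self):
        b = BandSet(f_peak=127.75)
        assert b.dbs == ((126.75, 128.75),)
        assert b.dipole == ((11.5, 12.5),)
        assert b.movement == ((1.0, 11.5), (12.5, 15.0))


def fake_sweep(method, values, rmse_rows):
    rmse = pd.DataFrame(rmse_rows, index=["dipole", "movement", "dbs"],
                        columns=values, dtype=float)
    from megdbs.evaluation import PARAMETER_NAMES

    return SweepResult(method=method, parameter_name=PARAMETER_NAMES[method],
                       parameter_values=np.asarray(values, float), rmse=rmse,
                       baseline={"dipole": 1.0, "movement": 1.0, "dbs": 1.0})


class TestRobustness:
    def test_constant_rmse_has_zero_spread(self):
        sw = fake_sweep("hampel", [1, 2, 3], np.ones((3, 3)))
        mean, sd = robustness(sw)
        assert (mean, sd) == (1.0, 0.0)

    def test_sample_standard_deviation_hand_case(self):
        sw = fake_sweep("hampel", [1, 2],
                        [[9, 9], [9, 9], [0.1, 0.2]])
        mean, sd = robustness(sw)   # dbs band only for hampel
        assert mean == pytest.approx(0.15)
        assert sd == pytest.approx(0.070710678, abs=1e-8)

    def test_pooling_covers_three_bands_for_icami(self):
        rows = np.arange(12.0).reshape(3, 4)
        sw = fake_sweep("icami", [5, 10, 15, 20], rows)
        mean, sd = robustness(sw)
        assert mean == pytest.approx(rows.ravel().mean())
        assert sd == pytest.approx(np.std(rows.ravel(), ddof=1))

    def test_single_value_rejected(self):
        sw = fake_sweep("hampel", [1], [[1.0], [1.0], [1.0]])
        with pytest.raises(ValueError, match="two"):
            robustness(sw)


class TestOptimalSensor:
    def test_unique_minimum_selected(self):
        rows = [[1, 1, 1], [1, 1, 1], [3.0, 0.5, 2.0]]
        assert select_optimal_sensor(fake_sweep("hampel", [1, 2, 3], rows)) == 2

    def test_single_value_returned(self):
        assert select_optimal_sensor(
            fake_sweep("hampel", [4], [[1.0], [1.0], [1.0]])) == 4

    def test_ties_break_toward_weaker_cleaning(self):
        flat = np.ones((3, 4))
        assert select_optimal_sensor(fake_sweep("hampel", [1, 2, 3, 4], flat)) == 4
        assert select_optimal_sensor(fake_sweep("s3p", [1, 2, 3, 4], flat)) == 1
        assert select_optimal_sensor(fake_sweep("icami", [5, 10, 20, 40], flat)) == 5
        assert select_optimal_sensor(
            fake_sweep("tsss", [0.95, 0.9, 0.8, 0.6], flat)) == 0.95


class TestOptimalSource:
    def test_small_improvement_stops_walk(self):
        # 0.50 -> 0.60 accepted (+0.10), 0.60 -> 0.605 rejected (+0.005)
        assert select_optimal_source([1, 2, 3], [0.50, 0.60, 0.605]) == 2

    def test_monotone_decreasing_keeps_initial_value(self):
        assert select_optimal_source([1, 2, 3], [0.5, 0.4, 0.3]) == 1

    def test_steady_improvement_reaches_end(self):
        assert select_optimal_source([1, 2, 3], [0.5, 0.52, 0.54]) == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_optimal_source([], [])


class TestReport:
    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        sw = fake_sweep("hampel", [1.0, 2.0], rng.random((3, 2)))
        report = make_report(None, {"hampel": sw})
        assert set(report.tables) >= {"rmse_hampel", "robustness",
                                      "optimal_sensor"}
        # one row per band, one column per parameter value plus the baseline
        assert report.tables["rmse_hampel"].shape == (3, 3)
        report.save(tmp_path / "rep")
        back = Report.load(tmp_path / "rep")
        for name, df in report.tables.items():
            got = back.tables[name]
            pd.testing.assert_index_equal(df.index, got.index)
            for col in df.columns:
                a, b = df[col].to_numpy(), got[col].to_numpy()
                if a.dtype.kind == "f":
                    assert np.allclose(a.astype(float), b.astype(float),
                                       rtol=0, atol=0, equal_nan=True)
                else:
                    assert list(a) == list(b)
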