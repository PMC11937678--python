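"""Online-pipeline unit tests: filters, ERSP arithmetic, calibration, replay."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import smrloop as sl
from smrloop.recordings import EEGRecording
from smrloop.realtime import run_closed_loop_replay

FS = 1000.0


def _recording(signals: dict[str, np.ndarray]) -> EEGRecording:
    labels = list(signals)
    return EEGRecording(np.vstack([signals[c] for c in labels]), FS, labels)


class TestLargeLaplacian:
    def test_common_mode_rejected(self):
        x = np.random.default_rng(0).normal(size=1000)
        rec = _recording({c: x for c in ("C3", "F3", "P3", "T7", "Cz")})
        np.testing.assert_allclose(sl.large_laplacian(rec), 0.0, atol=1e-12)

    def test_identity_with_zero_neighbors(self):
        s = np.sin(np.arange(1000) / 50.0)
        z = np.zeros(1000)
        rec = _recording({"C3": s, "F3": z, "P3": z, "T7": z, "Cz": z})
        np.testing.assert_allclose(sl.large_laplacian(rec), s)

    def test_constant_arithmetic(self):
        vals = {"C3": 4.0, "F3": 1.0, "P3": 2.0, "T7": 3.0, "Cz": 6.0}
        rec = _recording({c: np.full(100, v) for c, v in vals.items()})
        np.testing.assert_allclose(sl.large_laplacian(rec), 1.0)

    def test_missing_channel_named_in_error(self):
        rec = _recording({"C3": np.zeros(100), "F3": np.zeros(100)})
        with pytest.raises(KeyError, match="P3"):
            sl.large_laplacian(rec)


class TestBufferFilter:
    def test_zero_phase_on_passband_tone(self):
        t = np.arange(5 * FS) / FS
        x = np.sin(2 * np.pi * 10 * t)
        y = sl.buffer_filter(x, FS)
        # cross-correlate interior segments: peak at zero lag
        a = x[1000:4000]
        b = y[1000:4000]
        lags = np.arange(-20, 21)
        xc = [np.dot(a, np.roll(b, k)) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_notch_kills_50hz(self):
        t = np.arange(5 * FS) / FS
        y = sl.buffer_filter(np.sin(2 * np.pi * 50 * t), FS)
        interior = y[1000:4000]
        assert np.sqrt((interior**2).mean()) < 0.01 / np.sqrt(2)

    def test_dc_removed(self):
        y = sl.buffer_filter(np.full(5000, 7.5), FS)
        assert np.abs(y[1000:4000]).max() < 0.05

    def test_short_buffer_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sl.buffer_filter(np.zeros(10), FS)


class TestSTFTPower:
    def test_tone_concentrates_at_its_bin(self):
        t = np.arange(FS) / FS
        s = sl.stft_power(np.sin(2 * np.pi * 10 * t), FS)
        assert s.power[10] >= 100 * s.power[20]
        assert s.freqs[1] - s.freqs[0] == 1.0

    def test_zero_signal_zero_power(self):
        s = sl.stft_power(np.zeros(1000), FS)
        np.testing.assert_array_equal(s.power, 0.0)

    def test_amplitude_doubling_quadruples_power(self):
        t = np.arange(FS) / FS
        x = np.sin(2 * np.pi * 11 * t)
        p1 = sl.stft_power(x, FS).power
        p2 = sl.stft_power(2 * x, FS).power
        np.testing.assert_allclose(p2, 4 * p1, atol=1e-12)

    def test_uses_final_second_of_longer_buffer(self):
        x = np.concatenate([np.zeros(4000), np.ones(1000)])
        s = sl.stft_power(x, FS)
        assert s.power.sum() > 0


class TestERSPArithmetic:
    def test_reference_mean(self):
        ref = sl.compute_reference([np.array([2.0]), np.array([4.0])])
        assert ref[0] == 3.0
        with pytest.raises(ValueError):
            sl.compute_reference([])

    @pytest.mark.parametrize("factor,expected", [
        (1.0, 0.0), (0.7, -30.0), (2.0, 100.0), (0.0, -100.0),
    ])
    def test_percent_change(self, factor, expected):
        ref = np.array([5.0, 10.0])
        np.testing.assert_allclose(sl.ersp(factor * ref, ref), expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            sl.ersp(np.array([1.0]), np.array([0.0]))

    @given(st.lists(st.floats(0.01, 1e6), min_size=3, max_size=10))
    def test_lower_bound_minus_100(self, power):
        ref = np.full(len(power), 100.0)
        assert np.all(sl.ersp(np.array(power), ref) >= -100.0)


class TestSMRAlpha:
    def test_band_mean(self):
        freqs = np.arange(0, 20)
        bins = np.zeros(20)
        bins[8:14] = [-10, -20, -30, -40, -50, -60]
        assert sl.smr_alpha(bins, freqs) == pytest.approx(-35.0)

    def test_foi_selection(self):
        freqs = np.arange(0, 20)
        bins = np.arange(20.0)
        assert sl.smr_alpha(bins, freqs, mode="foi", foi=11) == 11.0

    def test_foi_without_calibration_rejected(self):
        with pytest.raises(ValueError):
            sl.smr_alpha(np.zeros(20), np.arange(20), mode="foi")


class TestCalibrateFOI:
    @staticmethod
    def _map(values):
        return SimpleNamespace(
            freqs=np.arange(1, 41), times=np.arange(1, 18, 0.1),
            values=values,
        )

    def test_injected_erd_identified(self):
        values = np.zeros((40, 170))
        values[9, 60:120] = -40.0          # 10 Hz bin (freqs start at 1)
        assert sl.calibrate_foi(self._map(values)) == 10

    def test_tie_breaks_to_lowest_frequency(self):
        values = np.zeros((40, 170))
        values[8, 60:120] = -40.0          # 9 Hz
        values[11, 60:120] = -40.0         # 12 Hz
        assert sl.calibrate_foi(self._map(values)) == 9

    def test_flat_spectrum_warns_and_returns_lowest(self):
        with pytest.warns(UserWarning, match="no negative"):
            foi = sl.calibrate_foi(self._map(np.zeros((40, 170))))
        assert foi == 8

    def test_generator_erd_recovered(self, small_eeg):
        ersp_map = sl.ersp_timefreq_map(small_eeg)
        assert sl.calibrate_foi(ersp_map) == 10


class TestSmoothing:
    def test_partial_and_sliding_window(self):
        assert sl.smooth_smr([0.0, -30.0, -60.0]) == -30.0
        hist = list(range(1, 11))
        assert sl.smooth_smr(hist) == 5.5
        assert sl.smooth_smr(hist + [11]) == 6.5

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_mean_within_range(self, hist):
        s = sl.smooth_smr(hist)
        assert min(hist[-10:]) - 1e-9 <= s <= max(hist[-10:]) + 1e-9


class TestFrameMapping:
    CAL = sl.FeedbackCalibration(foi=10, p25=-40.0, p75=0.0)

    def test_anchor_points(self):
        assert sl.map_to_frame(self.CAL.p25, self.CAL) == 20
        assert sl.map_to_frame(self.CAL.p75, self.CAL) == 1

    def test_midpoint_rounds_half_up(self):
        mid = (self.CAL.p25 + self.CAL.p75) / 2
        assert sl.map_to_frame(mid, self.CAL) == 11

    def test_clipping_beyond_anchors(self):
        assert sl.map_to_frame(-500.0, self.CAL) == 20
        assert sl.map_to_frame(500.0, self.CAL) == 1

    def test_degenerate_calibration_rejected(self):
        cal = sl.FeedbackCalibration(foi=10, p25=0.0, p75=0.0)
        with pytest.raises(ValueError):
            sl.map_to_frame(0.0, cal)

    @given(st.floats(-200, 200))
    def test_monotone_nonincreasing_in_smr(self, smr):
        f1 = sl.map_to_frame(smr, self.CAL)
        f2 = sl.map_to_frame(smr + 1.0, self.CAL)
        assert 1 <= f2 <= f1 <= 20


class TestReplay:
    def test_deterministic(self, small_eeg):
        cal = sl.FeedbackCalibration(foi=10, p25=-30.0, p75=0.0)
        t1 = run_closed_loop_replay(small_eeg, calibration=cal)
        t2 = run_closed_loop_replay(small_eeg, calibration=cal)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_causality_under_truncation(self, small_eeg):
        """Removing future samples leaves past ticks untouched."""
        full = run_closed_loop_replay(small_eeg, smr_mode="band")
        cut = round(40.0 * small_eeg.sampling_rate)
        truncated = EEGRecording(
            small_eeg.signal[:, :cut], small_eeg.sampling_rate,
            small_eeg.channel_labels,
            small_eeg.events[small_eeg.events.onset_sample < cut],
        )
        part = run_closed_loop_replay(truncated, smr_mode="band")
        n = len(part.table)
        pd.testing.assert_frame_equal(part.table, full.table.iloc[:n])

    def test_task_smr_below_rest(self, small_eeg):
        trace = run_closed_loop_replay(small_eeg, smr_mode="foi", foi=10)
        tab = trace.table.copy()
        tab["tt"] = tab.tick_s % 17.0
        task = tab[(tab.tt >= 7) & (tab.tt <= 12)].smoothed_smr.mean()
        rest = tab[(tab.tt >= 2) & (tab.tt <= 5)].smoothed_smr.mean()
        assert task < rest

    def test_frames_cover_valid_range(self, small_eeg):
        trace = run_closed_loop_replay(small_eeg, smr_mode="foi", foi=10)
        cal = sl.calibrate_from_trace(trace, foi=10)
        closed = run_closed_loop_replay(small_eeg, calibration=cal)
        frames = closed.table.frame.dropna()
        assert frames.between(1, 20).all()
        assert frames.nunique() > 5        # feedback actually modulates

    def test_short_recording_rejected(self):
        rec = EEGRecording(np.zeros((5, 1000)), FS,
                           ["C3", "F3", "P3", "T7", "Cz"])
        with pytest.raises(ValueError):
            run_closed_loop_replay(rec, smr_mode="band")

    def test_erd_depth_ordering_recovered(self):
        """Deeper simulated desynchronization -> more negative task SMR."""
        means = []
        for depth in (0.2, 0.6):
            rec = sl.generate_eeg_session(
                sl.EEGSimConfig(n_trials=4, erd_depth=depth, seed=44)
            )
            tab = run_closed_loop_replay(rec, smr_mode="foi", foi=10).table
            tab["tt"] = tab.tick_s % 17.0
            means.append(tab[(tab.tt >= 7) & (tab.tt <= 12)].raw_smr.mean())
        assert means[1] < means[0] < 0
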