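"""Smoothing, fiducial detection and PTT extraction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pttbp.beat_detection import (
    BeatAnnotations,
    PTTSeries,
    check_signal_fluctuation,
    compute_ptt_series,
    detect_ppg_peaks,
    detect_r_peaks,
    extract_ptt,
    sliding_window_filter,
)
from pttbp.synthetic import (
    CohortConfig,
    generate_cohort,
    render_waveforms,
)


class TestSlidingWindowFilter:
    def test_constant_signal_unchanged(self):
        out = sliding_window_filter(np.full(4, 5.0), fs=250.0, window_ms=10.0)
        np.testing.assert_array_equal(out, [5, 5, 5, 5])

    def test_single_sample_window_is_identity(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        np.testing.assert_array_equal(
            sliding_window_filter(x, fs=250.0, window_ms=4.0), x
        )

    def test_three_sample_window_matches_convolution(self):
        # 10 ms at 250 Hz rounds to a 3-sample centered window
        x = np.array([0.0, 3.0, 0.0, 3.0, 0.0])
        out = sliding_window_filter(x, fs=250.0, window_ms=10.0)
        expected_interior = np.convolve(x, np.ones(3) / 3, mode="valid")
        np.testing.assert_allclose(out[1:-1], expected_interior)
        # shrinking edges: plain samples at the ends (half-width 0)
        assert out[0] == x[0] and out[-1] == x[-1]

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="exceeds signal length"):
            sliding_window_filter(np.zeros(3), fs=250.0, window_ms=1000.0)

    @given(
        st.lists(st.floats(-10, 10), min_size=25, max_size=60),
        st.floats(4.0, 80.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_output_length_and_range_preserved(self, samples, window_ms):
        x = np.array(samples)
        out = sliding_window_filter(x, fs=250.0, window_ms=window_ms)
        assert len(out) == len(x)
        assert out.min() >= x.min() - 1e-12
        assert out.max() <= x.max() + 1e-12


class TestRPeakDetection:
    def test_flat_signal_yields_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no R-peaks"):
            peaks = detect_r_peaks(np.zeros(2500), fs=250.0)
        assert len(peaks) == 0

    def test_noise_free_peaks_within_one_sample(self, noise_free_cohort):
        fs = 250.0
        for law in noise_free_cohort.subjects[:2]:
            truth = noise_free_cohort.truth[(law.subject_id, "estimation_test")]
            rec = render_waveforms(truth, fs)
            ecg = sliding_window_filter(rec.ecg, fs, 10.0)
            det = detect_r_peaks(ecg, fs)
            r_true = np.round(truth.r_time_s * fs).astype(int)
            assert len(det) >= len(r_true) - 1
            for rt in r_true:
                assert np.min(np.abs(det - rt)) <= 1

    def test_refractory_period_enforced(self, default_cohort):
        rec = default_cohort.sessions[0].record
        det = detect_r_peaks(sliding_window_filter(rec.ecg, rec.fs, 10.0), rec.fs)
        assert np.all(np.diff(det) >= int(0.25 * rec.fs))


class TestPPGPeakDetection:
    def test_programmed_offsets_recovered(self):
        """PPG pulses rendered 200 ms after each R-peak pair at 200 ms."""
        fs = 250.0
        r = np.arange(5) * 250 + 100  # 1 s apart
        ppg = np.zeros(1600)
        for ri in r:
            center = ri + 50  # 200 ms at 250 Hz
            w = np.arange(center - 30, center + 31)
            ppg[w] += np.cos(np.pi * (w - center) / 60.0) ** 2
        ann = detect_ppg_peaks(ppg, fs, r)
        assert len(ann.matched_pairs) == 4  # one per complete R-R interval
        for ri, pi in ann.matched_pairs:
            assert pi - ri == 50

    def test_zero_ppg_gives_no_pairs(self):
        ann = detect_ppg_peaks(np.zeros(1000), 250.0, np.array([100, 350, 600]))
        assert ann.matched_pairs == []

    def test_peak_outside_physiologic_window_unmatched(self):
        """A pulse peaking 50 ms after the R-wave is sub-physiologic."""
        fs = 250.0
        r = np.array([100, 350])
        ppg = np.zeros(700)
        center = 100 + 12  # ~50 ms
        w = np.arange(center - 10, center + 11)
        ppg[w] = np.cos(np.pi * (w - center) / 20.0) ** 2
        ann = detect_ppg_peaks(ppg, fs, r)
        assert ann.matched_pairs == []

    def test_fewer_than_two_r_peaks_warns(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            ann = detect_ppg_peaks(np.zeros(1000), 250.0, np.array([500]))
        assert ann.matched_pairs == []

    def test_pairing_is_injective(self, default_cohort):
        rec = default_cohort.sessions[0].record
        ecg = sliding_window_filter(rec.ecg, rec.fs, 10.0)
        ppg = sliding_window_filter(rec.ppg, rec.fs, 10.0)
        ann = detect_ppg_peaks(ppg, rec.fs, detect_r_peaks(ecg, rec.fs))
        rs = [p[0] for p in ann.matched_pairs]
        ps = [p[1] for p in ann.matched_pairs]
        assert len(set(rs)) == len(rs) and len(set(ps)) == len(ps)


class TestPTTSeries:
    def test_single_pair_arithmetic(self):
        ann = BeatAnnotations(np.array([0, 250]), np.array([50]), [(0, 50)])
        series = compute_ptt_series(ann, fs=250.0)
        assert series.ptt_ms[0] == pytest.approx(200.0)
        assert series.beat_times_s[0] == 0.0

    def test_deltas_are_successive_differences(self):
        series = PTTSeries(np.array([200.0, 210.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(series.deltas_ms, [10.0])

    def test_programmed_ramp_recovered_within_one_sample(self):
        """PTT ramping 180→220 ms across a session is tracked beat-for-beat."""
        import pttbp.synthetic as syn

        n = 40
        r_times = 0.5 + np.arange(n) * 0.9
        ptt = np.linspace(180.0, 220.0, n)
        truth = syn.TruthTable(
            subject_id="S", session_label="estimation_test", posture="sitting",
            r_time_s=r_times, true_ptt_ms=ptt,
            true_sbp_mmHg=np.full(n, 115.0), true_dbp_mmHg=np.full(n, 72.0),
        )
        rec = render_waveforms(truth, 250.0)
        series = extract_ptt(rec)
        assert len(series) >= n - 1
        for bt, p in zip(series.beat_times_s, series.ptt_ms):
            i = np.argmin(np.abs(r_times - bt))
            assert abs(p - ptt[i]) <= 4.0  # one sample period


class TestFluctuationCheck:
    def _series(self, ptt):
        ptt = np.asarray(ptt, dtype=float)
        return PTTSeries(ptt, np.arange(len(ptt), dtype=float))

    def test_constant_series_valid(self):
        assert check_signal_fluctuation(self._series([200.0] * 20)).valid

    def test_high_cv_invalid(self):
        rng = np.random.default_rng(0)
        ptt = np.abs(rng.normal(200, 100, size=50)) + 1
        report = check_signal_fluctuation(self._series(ptt))
        assert not report.valid and report.cv > 0.2

    def test_too_few_beats_invalid(self):
        report = check_signal_fluctuation(self._series([200.0] * 9))
        assert not report.valid and report.reason == "insufficient beats"

    def test_unmatched_fraction_trips_threshold(self):
        series = PTTSeries(
            np.full(12, 200.0), np.arange(12, dtype=float), n_cycles=20
        )
        report = check_signal_fluctuation(series)
        assert not report.valid and "unmatched" in report.reason
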