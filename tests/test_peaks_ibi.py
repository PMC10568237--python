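"""Beat detection, double-peak correction, IBI construction and reliable frames."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from afibkit.peaks_ibi import (
    IBISeries,
    PeakSeries,
    build_ibi,
    correct_double_peaks,
    detect_beats,
    detect_peaks,
    find_reliable_frames,
)
from afibkit.signal_io import Recording


def _gauss_train(times_s, fs=250.0, dur=None, sigma=0.012):
    dur = dur if dur is not None else times_s[-1] + 0.5
    t = np.arange(0, dur, 1 / fs)
    x = np.zeros_like(t)
    for tp in times_s:
        x += np.exp(-0.5 * ((t - tp) / sigma) ** 2)
    return Recording(x, fs=fs, subject_id="s")


class TestDetectPeaks:
    def test_regular_gaussian_train(self):
        times = 0.5 + 0.8 * np.arange(10)
        rec = _gauss_train(times)
        pk = detect_peaks(rec)
        assert len(pk) == 10
        np.testing.assert_allclose(np.diff(pk.indices), 200, atol=1)

    def test_flat_signal_no_peaks(self):
        rec = Recording(np.zeros(5000), fs=250, subject_id="s")
        assert len(detect_peaks(rec)) == 0

    def test_sine_crests(self):
        fs = 250.0
        t = np.arange(0, 10, 1 / fs)
        rec = Recording(np.sin(2 * np.pi * t), fs=fs, subject_id="s")
        pk = detect_peaks(rec)
        assert len(pk) == 10
        crests = (0.25 + np.arange(10)) * fs
        np.testing.assert_allclose(pk.indices, crests, atol=1)


class TestCorrectDoublePeaks:
    def test_larger_of_close_pair_kept(self):
        pk = PeakSeries(np.array([100, 130, 400]), fs=250.0,
                        amplitudes=np.array([1.0, 0.6, 0.9]))
        out = correct_double_peaks(pk, min_sep_ms=250.0)
        np.testing.assert_array_equal(out.indices, [100, 400])

    def test_no_violation_is_identity(self):
        pk = PeakSeries(np.array([0, 200, 400]), fs=250.0,
                        amplitudes=np.array([1.0, 1.0, 1.0]))
        out = correct_double_peaks(pk)
        np.testing.assert_array_equal(out.indices, pk.indices)

    def test_three_mutually_close_keeps_global_max(self):
        pk = PeakSeries(np.array([100, 120, 140]), fs=250.0,
                        amplitudes=np.array([0.5, 0.9, 0.7]))
        out = correct_double_peaks(pk, min_sep_ms=250.0)
        np.testing.assert_array_equal(out.indices, [120])

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.floats(0.1, 10.0)),
            min_size=2,
            max_size=30,
            unique_by=lambda p: p[0],
        )
    )
    def test_idempotent(self, pairs):
        pairs.sort()
        idx = np.array([p[0] for p in pairs])
        amp = np.array([p[1] for p in pairs])
        pk = PeakSeries(idx, fs=250.0, amplitudes=amp)
        once = correct_double_peaks(pk)
        twice = correct_double_peaks(once)
        np.testing.assert_array_equal(once.indices, twice.indices)
        assert np.all(np.diff(once.indices) >= 250.0 * 250.0 / 1000.0)


class TestBuildIBI:
    def test_arithmetic_and_validity(self):
        pk = PeakSeries(np.array([0, 200, 400]), fs=250.0)
        ibi = build_ibi(pk, record_len=500)
        np.testing.assert_allclose(ibi.intervals_ms, [800.0, 800.0])
        assert ibi.valid.all()
        assert (ibi.min_ibi_ms, ibi.max_ibi_ms) == (270.0, 1500.0)

    def test_out_of_bounds_interval_flagged_and_pruned_to_zero(self):
        pk = PeakSeries(np.array([0, 50, 300]), fs=250.0)
        ibi = build_ibi(pk, record_len=400)
        np.testing.assert_allclose(ibi.intervals_ms, [200.0, 1000.0])
        np.testing.assert_array_equal(ibi.valid, [False, True])
        np.testing.assert_allclose(ibi.masked_intervals_ms, [0.0, 1000.0])
        assert np.all(ibi.masked_expanded[:50] == 0.0)

    def test_expansion_covers_record_samplewise(self):
        pk = PeakSeries(np.array([100, 300, 700]), fs=250.0)
        ibi = build_ibi(pk, record_len=1000)
        assert ibi.expanded.size == 1000
        assert np.all(ibi.expanded[:100] == 800.0)  # edge carries nearest gap
        assert np.all(ibi.expanded[100:300] == 800.0)
        assert np.all(ibi.expanded[300:700] == 1600.0)
        assert np.all(ibi.expanded[700:] == 1600.0)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            build_ibi(PeakSeries(np.array([5]), fs=250.0), record_len=100)

    @given(
        st.lists(st.integers(280, 1400), min_size=2, max_size=40)
    )
    def test_roundtrip_intervals_and_duration(self, gaps_ms):
        fs = 250.0
        gaps = np.array(gaps_ms, dtype=float)
        idx = np.concatenate(([0], np.cumsum(np.round(gaps * fs / 1000)))).astype(int)
        ibi = build_ibi(PeakSeries(idx, fs=fs), record_len=int(idx[-1]) + 10)
        # quantization by one sample period at most
        np.testing.assert_allclose(ibi.intervals_ms, gaps, atol=1000 / fs)
        # sum of gap durations equals first-to-last peak time
        assert ibi.intervals_ms.sum() == pytest.approx(
            (idx[-1] - idx[0]) * 1000 / fs
        )


class TestReliableFrames:
    def _uniform_ibi(self, n_s=20, gap_s=0.5, fs=250.0):
        idx = np.arange(0, int(n_s * fs) + 1, int(gap_s * fs))
        return build_ibi(PeakSeries(idx, fs=fs), record_len=int(n_s * fs))

    def test_all_valid_frame_count(self):
        ibi = self._uniform_ibi()
        frames = find_reliable_frames(ibi, window_s=8, stride_s=2)
        assert len(frames) == 7  # floor((20-8)/2)+1

    def test_invalid_interval_excludes_overlapping_frames(self):
        fs = 250.0
        # 0.5 s gaps, but one 1.8 s (invalid) gap spanning t=9..10.8 s
        idx = list(np.arange(0, int(9 * fs) + 1, int(0.5 * fs)))
        idx += list(np.arange(int(10.8 * fs), int(20 * fs), int(0.5 * fs)))
        ibi = build_ibi(PeakSeries(np.array(idx), fs=fs), record_len=int(20 * fs))
        frames = find_reliable_frames(ibi, window_s=8, stride_s=2)
        for f in frames:
            assert f.end_sample <= 9 * fs or f.start_sample >= 10.8 * fs

    def test_all_invalid_yields_empty(self):
        idx = np.arange(0, 5000, 50)  # 200 ms gaps, all below the lower bound
        ibi = build_ibi(PeakSeries(idx, fs=250.0), record_len=5000)
        assert find_reliable_frames(ibi, window_s=8, stride_s=2) == []

    def test_frames_have_min_peaks_and_valid_intervals(self):
        ibi = self._uniform_ibi()
        for f in find_reliable_frames(ibi, 8, 2, min_peaks=3):
            assert f.n_peaks >= 3
            assert np.all(f.intervals_ms() > 0)


def test_waveform_roundtrip_recovers_planted_rr(nsr_recording):
    rec, truth = nsr_recording
    from afibkit.preprocess import preprocess

    pk = detect_beats(preprocess(rec))
    assert len(pk) == len(truth)
    assert np.max(np.abs(pk.indices - truth)) <= 2
    planted = np.diff(truth) * 1000.0 / rec.fs
    detected = np.diff(pk.indices) * 1000.0 / rec.fs
    np.testing.assert_allclose(detected, planted, atol=1000.0 / rec.fs)
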