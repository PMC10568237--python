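"""Record reading, rhythm splitting, segmentation and resampling."""
import numpy as np
import pytest

from afibkit.signal_io import (
    Modality,
    Recording,
    Rhythm,
    RhythmAnnotation,
    RhythmBlock,
    downsample,
    read_record,
    segment_fixed,
    split_by_rhythm,
    write_record_csv,
)


def _write_csv(path, rows):
    path.write_text("\n".join(rows) + "\n")


class TestReadRecord:
    def test_amplitude_only_csv_with_fs_override(self, tmp_path):
        p = tmp_path / "amp.csv"
        _write_csv(p, [f"{v:.3f}" for v in np.sin(np.arange(500) / 10)])
        rec = read_record(p, fs_override=250)
        assert rec.n_samples == 500
        assert rec.fs == 250

    def test_fs_inferred_from_time_column(self, tmp_path):
        p = tmp_path / "timed.csv"
        times = np.arange(200) * 0.004  # 4 ms spacing
        _write_csv(p, ["time,amp"] + [f"{t:.6f},{i}" for i, t in enumerate(times)])
        rec = read_record(p)
        assert rec.fs == pytest.approx(250.0)
        assert rec.samples[3] == 3

    def test_amplitude_only_without_fs_is_an_error(self, tmp_path):
        p = tmp_path / "amp.csv"
        _write_csv(p, ["1.0", "2.0"])
        with pytest.raises(ValueError):
            read_record(p)

    def test_empty_file_raises_no_samples(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="no samples"):
            read_record(p, fs_override=250)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_record(tmp_path / "nope.csv")

    def test_csv_roundtrip(self, tmp_path):
        rec = Recording(np.linspace(-1, 1, 400), fs=100.0, subject_id="s1")
        p = tmp_path / "rt.csv"
        write_record_csv(rec, p)
        back = read_record(p, fs_override=None)
        assert back.fs == pytest.approx(100.0, rel=1e-3)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)

    def test_wfdb_format16_first_channel(self, tmp_path):
        sig = np.vstack(
            [np.arange(100, dtype="<i2"), 1000 + np.arange(100, dtype="<i2")]
        ).T
        (tmp_path / "r16.dat").write_bytes(sig.astype("<i2").tobytes())
        (tmp_path / "r16.hea").write_text(
            "r16 2 250 100\nr16.dat 16 200 12 0 0 0 0 I\nr16.dat 16 200 12 0 0 0 0 II\n"
        )
        rec = read_record(tmp_path / "r16.hea")
        assert rec.fs == 250
        np.testing.assert_array_equal(rec.samples, np.arange(100))
        ch2 = read_record(tmp_path / "r16.hea", channel=1)
        np.testing.assert_array_equal(ch2.samples, 1000 + np.arange(100))

    def test_wfdb_format212(self, tmp_path):
        vals = np.array([0, 1, -1, 100, -100, 2047, -2048, 7, 8, -9], dtype=np.int32)
        packed = bytearray()
        for a, b in vals.reshape(-1, 2):
            a &= 0xFFF
            b &= 0xFFF
            packed += bytes([a & 0xFF, ((b >> 4) & 0xF0) | ((a >> 8) & 0x0F), b & 0xFF])
        (tmp_path / "r212.dat").write_bytes(bytes(packed))
        (tmp_path / "r212.hea").write_text("r212 1 250 10\nr212.dat 212 200 12 0 0 0 0 ECG\n")
        rec = read_record(tmp_path / "r212.hea")
        np.testing.assert_array_equal(rec.samples, vals)


class TestRecordingInvariants:
    def test_rejects_empty_and_bad_fs(self):
        with pytest.raises(ValueError):
            Recording(np.array([]), fs=250)
        with pytest.raises(ValueError):
            Recording(np.ones(10), fs=0)
        with pytest.raises(ValueError):
            Recording(np.ones(10), fs=250, subject_id="")


class TestSplitByRhythm:
    def _rec(self, n=20000):
        return Recording(np.arange(n, dtype=float), fs=250, subject_id="s")

    def test_two_rhythm_blocks(self):
        ann = RhythmAnnotation(((0, 10000, "NSR"), (10000, 20000, "AFIB")))
        blocks = split_by_rhythm(self._rec(), ann)
        assert [b.label for b in blocks] == [Rhythm.NSR, Rhythm.AFIB]
        assert blocks[0].source_interval == (0, 10000)
        np.testing.assert_array_equal(
            blocks[1].recording.samples, np.arange(10000, 20000)
        )

    def test_keep_filter(self):
        ann = RhythmAnnotation(((0, 10000, "NSR"), (10000, 20000, "AFIB")))
        blocks = split_by_rhythm(self._rec(), ann, keep={"AFIB"})
        assert len(blocks) == 1 and blocks[0].label is Rhythm.AFIB

    def test_other_dropped_and_empty(self):
        ann = RhythmAnnotation(((0, 5000, "OTHER"),))
        assert split_by_rhythm(self._rec(), ann) == []
        assert split_by_rhythm(self._rec(), RhythmAnnotation(())) == []

    def test_interval_past_end_is_an_error(self):
        ann = RhythmAnnotation(((0, 30000, "NSR"),))
        with pytest.raises(ValueError):
            split_by_rhythm(self._rec(), ann)

    def test_slices_reconstruct_index_space(self):
        ann = RhythmAnnotation(
            ((0, 4000, "NSR"), (4000, 9000, "OTHER"), (9000, 20000, "AFIB"))
        )
        covered = sorted(
            (s, e) for s, e, _ in ann.intervals
        )
        # intervals tile without overlap; kept blocks carry the parent slice
        for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
            assert e1 <= s2
        for b in split_by_rhythm(self._rec(), ann):
            s, e = b.source_interval
            np.testing.assert_array_equal(b.recording.samples, np.arange(s, e))

    def test_annotation_rejects_overlap(self):
        with pytest.raises(ValueError):
            RhythmAnnotation(((0, 100, "NSR"), (50, 200, "AFIB")))

    def test_annotation_csv(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("start,end,label\n0,100,NSR\n100,300,AFIB\n")
        ann = RhythmAnnotation.from_csv(p)
        assert ann.intervals == ((0, 100, Rhythm.NSR), (100, 300, Rhythm.AFIB))


class TestSegmentFixed:
    @pytest.mark.parametrize(
        "dur_s, window_s, expect", [(95, 30, 3), (30, 30, 1), (29, 30, 0)]
    )
    def test_window_counts(self, dur_s, window_s, expect):
        rec = Recording(np.zeros(int(dur_s * 50)), fs=50, subject_id="s")
        assert len(segment_fixed(rec, window_s)) == expect

    def test_starts_and_total_length(self):
        rec = Recording(np.arange(95 * 50, dtype=float), fs=50, subject_id="s")
        segs = segment_fixed(rec, 30)
        starts = [int(s.samples[0]) for s in segs]
        assert starts == [0, 1500, 3000]
        assert sum(s.n_samples for s in segs) <= rec.n_samples

    def test_bad_overlap(self):
        rec = Recording(np.zeros(100), fs=50, subject_id="s")
        with pytest.raises(ValueError):
            segment_fixed(rec, 1.0, overlap_s=1.0)


class TestDownsample:
    def test_sine_preserved(self):
        fs = 125.0
        t = np.arange(0, 20, 1 / fs)
        rec = Recording(np.sin(2 * np.pi * 1.0 * t), fs=fs, modality="PPG")
        out = downsample(rec, 50.0)
        assert out.fs == pytest.approx(50.0)
        assert abs(out.n_samples - rec.n_samples * 0.4) <= 1
        t2 = np.arange(out.n_samples) / out.fs
        mid = slice(50, out.n_samples - 50)
        assert np.max(np.abs(out.samples[mid] - np.sin(2 * np.pi * t2[mid]))) < 1e-6

    def test_identity_and_errors(self):
        rec = Recording(np.arange(100, dtype=float), fs=100, subject_id="s")
        out = downsample(rec, 100.0)
        np.testing.assert_array_equal(out.samples, rec.samples)
        with pytest.raises(ValueError):
            downsample(rec, 0)
        with pytest.raises(ValueError):
            downsample(rec, 200.0)


def test_block_label_must_be_binary():
    rec = Recording(np.ones(10), fs=10, subject_id="s")
    with pytest.raises(ValueError):
        RhythmBlock(recording=rec, label="OTHER")
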