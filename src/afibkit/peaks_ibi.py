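"""Beat detection and the inter-beat-interval (IBI) signal.

The detector finds local maxima of the conditioned waveform above an
adaptive threshold (a fraction of a blockwise upper-percentile amplitude
envelope) with a refractory minimum distance, then removes double
detections by keeping the larger of any too-close pair. From the surviving
beats we build the IBI series: per-gap intervals in ms, a validity mask
against physiological bounds, and a sample-and-hold expansion to record
length so every waveform sample carries the interval governing it.
Reliable analysis frames are sliding windows in which no intersecting
interval is invalid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from . import config as _cfg
from .signal_io import Recording


@dataclass
class PeakSeries:
    """Strictly increasing beat sample positions on one record."""

    indices: np.ndarray
    fs: float
    amplitudes: np.ndarray | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.shape != self.indices.shape:
                raise ValueError("amplitudes must align with indices")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class IBISeries:
    """Per-gap intervals (ms), validity mask and sample-aligned expansion."""

    intervals_ms: np.ndarray
    valid: np.ndarray
    expanded: np.ndarray
    peaks: PeakSeries
    min_ibi_ms: float
    max_ibi_ms: float

    def __len__(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def masked_intervals_ms(self) -> np.ndarray:
        """Intervals with invalid entries pruned to zero."""
        return np.where(self.valid, self.intervals_ms, 0.0)

    @property
    def masked_expanded(self) -> np.ndarray:
        out = self.expanded.copy()
        p = self.peaks.indices
        for i in np.flatnonzero(~self.valid):
            out[p[i] : p[i + 1]] = 0.0
        return out


@dataclass(frozen=True)
class ReliableFrame:
    """An analysis window whose every intersecting interval is valid."""

    start_sample: int
    end_sample: int
    peak_indices: np.ndarray  # sample positions of peaks inside the window
    fs: float

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)

    @property
    def start_s(self) -> float:
        return self.start_sample / self.fs

    def intervals_ms(self) -> np.ndarray:
        """Per-gap intervals between consecutive peaks inside the frame."""
        return np.diff(self.peak_indices) * 1000.0 / self.fs


def _adaptive_threshold(
    x: np.ndarray, fs: float, percentile: float, frac: float, block_s: float
) -> np.ndarray:
    """Blockwise upper-percentile envelope, linearly interpolated, times frac."""
    n = x.size
    blk = max(1, int(round(block_s * fs)))
    centers, vals = [], []
    for start in range(0, n, blk):
        seg = x[start : start + blk]
        centers.append(start + (seg.size - 1) / 2.0)
        vals.append(np.percentile(seg, percentile))
    env = np.interp(np.arange(n), centers, vals)
    return frac * env


def detect_peaks(
    rec: Recording,
    refractory_s: float = _cfg.DEFAULT_PEAK_REFRACTORY_S,
    threshold_frac: float = _cfg.DEFAULT_PEAK_THRESHOLD_FRAC,
    percentile: float = _cfg.DEFAULT_PEAK_PERCENTILE,
    block_s: float = _cfg.DEFAULT_PEAK_BLOCK_S,
    floor_frac: float = _cfg.DEFAULT_PEAK_FLOOR_FRAC,
) -> PeakSeries:
    """Detect beat peaks (ECG R-waves or PPG systolic crests).

    Expects a conditioned record (non-negative, min-max scaled); returns an
    empty series when fewer than one peak clears the threshold. The local
    envelope threshold is floored at ``floor_frac`` of the global upper
    percentile so filter ringing in silent stretches cannot fire.
    """
    x = rec.samples
    thr = _adaptive_threshold(x, rec.fs, percentile, threshold_frac, block_s)
    thr = np.maximum(thr, floor_frac * np.percentile(x, percentile))
    distance = max(1, int(round(refractory_s * rec.fs)))
    idx, _ = find_peaks(x, height=thr, distance=distance)
    return PeakSeries(indices=idx, fs=rec.fs, amplitudes=x[idx])


def correct_double_peaks(
    peaks: PeakSeries, min_sep_ms: float = _cfg.DEFAULT_DOUBLE_PEAK_MIN_SEP_MS
) -> PeakSeries:
    """Drop the smaller of any two peaks closer than ``min_sep_ms``.

    Iterated until no violating pair remains; idempotent. Requires
    amplitudes (without them the series is returned unchanged when no
    violation exists, otherwise an error is raised).
    """
    if len(peaks) < 2:
        return peaks
    min_sep = min_sep_ms * peaks.fs / 1000.0
    idx = list(peaks.indices)
    if peaks.amplitudes is None:
        if np.all(np.diff(peaks.indices) >= min_sep):
            return peaks
        raise ValueError("amplitudes required to resolve double peaks")
    amp = list(peaks.amplitudes)
    changed = True
    while changed:
        changed = False
        for i in range(len(idx) - 1):
            if idx[i + 1] - idx[i] < min_sep:
                drop = i if amp[i] < amp[i + 1] else i + 1
                del idx[drop], amp[drop]
                changed = True
                break
    return PeakSeries(indices=np.array(idx), fs=peaks.fs, amplitudes=np.array(amp))


def build_ibi(
    peaks: PeakSeries,
    record_len: int,
    min_ibi_ms: float = _cfg.DEFAULT_MIN_IBI_MS,
    max_ibi_ms: float = _cfg.DEFAULT_MAX_IBI_MS,
) -> IBISeries:
    """Build the IBI series: intervals, validity mask and expansion.

    The expansion assigns to each sample the interval of the gap containing
    it (samples before the first / after the last peak carry the nearest
    interval), so its length always equals ``record_len``.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to build an IBI series")
    p = peaks.indices
    if p[-1] > record_len:
        raise ValueError("peaks exceed record length")
    intervals = np.diff(p) * 1000.0 / peaks.fs
    valid = (intervals >= min_ibi_ms) & (intervals <= max_ibi_ms)
    expanded = np.empty(record_len, dtype=float)
    expanded[: p[0]] = intervals[0]
    for i in range(intervals.size):
        expanded[p[i] : p[i + 1]] = intervals[i]
    expanded[p[-1] :] = intervals[-1]
    return IBISeries(
        intervals_ms=intervals,
        valid=valid,
        expanded=expanded,
        peaks=peaks,
        min_ibi_ms=min_ibi_ms,
        max_ibi_ms=max_ibi_ms,
    )


def find_reliable_frames(
    ibi: IBISeries,
    window_s: float,
    stride_s: float,
    min_peaks: int = 2,
) -> list[ReliableFrame]:
    """Sliding windows in which every intersecting interval is valid.

    Interval ``i`` (spanning ``[p[i], p[i+1])``) intersects a window
    ``[start, end)`` iff ``p[i] < end`` and ``p[i+1] > start``. Windows with
    fewer than ``min_peaks`` peaks are not reliable.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    fs = ibi.peaks.fs
    n = ibi.expanded.size
    win = int(round(window_s * fs))
    step = max(1, int(round(stride_s * fs)))
    p = ibi.peaks.indices
    frames: list[ReliableFrame] = []
    for start in range(0, n - win + 1, step):
        end = start + win
        lo = np.searchsorted(p, start, side="left")
        hi = np.searchsorted(p, end, side="left")
        if hi - lo < min_peaks:
            continue
        a = np.searchsorted(p[1:], start, side="right")  # first interval ending after start
        b = np.searchsorted(p[:-1], end, side="left")  # intervals starting before end
        if a < b and not np.all(ibi.valid[a:b]):
            continue
        frames.append(
            ReliableFrame(
                start_sample=start,
                end_sample=end,
                peak_indices=p[lo:hi].copy(),
                fs=fs,
            )
        )
    return frames


def detect_beats(
    rec: Recording,
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
) -> PeakSeries:
    """Convenience: adaptive detection followed by double-peak correction."""
    raw = detect_peaks(
        rec,
        refractory_s=cfg.peak_refractory_s,
        threshold_frac=cfg.peak_threshold_frac,
        percentile=cfg.peak_percentile,
        block_s=cfg.peak_block_s,
        floor_frac=cfg.peak_floor_frac,
    )
    return correct_double_peaks(raw, cfg.double_peak_min_sep_ms)
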