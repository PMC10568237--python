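"""Waveform conditioning: smoothing, band-pass filtering, min-max scaling.

The chain is Savitzky-Golay smoothing (order 4, 19 frames), a zero-phase
2nd-order Butterworth band-pass at 0.5-20 Hz, then min-max normalization to
[0, 10]. The band-pass runs forward-backward so beat peak *positions*, which
drive everything downstream, are not shifted; for low-rate PPG the upper
cutoff is clamped below Nyquist.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, savgol_filter, sosfiltfilt

from . import config as _cfg
from .signal_io import Recording


@dataclass(frozen=True)
class FilterSpec:
    sg_order: int = _cfg.DEFAULT_SG_ORDER
    sg_frames: int = _cfg.DEFAULT_SG_FRAMES
    bp_order: int = _cfg.DEFAULT_BP_ORDER
    bp_low: float = _cfg.DEFAULT_BP_LOW_HZ
    bp_high: float = _cfg.DEFAULT_BP_HIGH_HZ
    norm_scale: float = _cfg.DEFAULT_NORM_SCALE

    def __post_init__(self):
        if self.sg_frames % 2 == 0 or self.sg_frames <= self.sg_order:
            raise ValueError("sg_frames must be odd and exceed sg_order")
        if not (0 < self.bp_low < self.bp_high):
            raise ValueError("need 0 < bp_low < bp_high")
        if self.norm_scale <= 0:
            raise ValueError("norm_scale must be positive")


def smooth(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Savitzky-Golay polynomial least-squares smoothing."""
    if rec.n_samples < spec.sg_frames:
        raise ValueError("record shorter than the smoothing window")
    y = savgol_filter(rec.samples, spec.sg_frames, spec.sg_order)
    return replace(rec, samples=y)


def effective_band(spec: FilterSpec, fs: float) -> tuple[float, float]:
    """Band edges actually used at ``fs``; the high edge is clamped to 0.4*fs."""
    high = min(spec.bp_high, 0.4 * fs)
    if spec.bp_low >= high:
        raise ValueError("band-pass low edge at or above effective high edge")
    return spec.bp_low, high


def bandpass(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    low, high = effective_band(spec, rec.fs)
    if high >= rec.fs / 2:
        raise ValueError("band-pass high edge at or above Nyquist")
    sos = butter(spec.bp_order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    y = sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=y)


def minmax_normalize(rec: Recording, scale: float = _cfg.DEFAULT_NORM_SCALE) -> Recording:
    """Affine rescale to exactly [0, scale]."""
    lo, hi = float(np.min(rec.samples)), float(np.max(rec.samples))
    if hi <= lo:
        raise ValueError("zero dynamic range")
    y = scale * (rec.samples - lo) / (hi - lo)
    return replace(rec, samples=y)


def preprocess(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Full conditioning chain: smooth -> band-pass -> min-max normalize."""
    return minmax_normalize(bandpass(smooth(rec, spec), spec), spec.norm_scale)
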