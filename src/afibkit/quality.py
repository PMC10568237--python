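"""Two-step signal-quality gate applied before classification.

A segment is classified only if (1) at least 75% of its inter-beat
intervals fall inside physiological bounds and (2) its mean beat-level SNR
exceeds 5 dB. The SNR estimator ensemble-averages the detected beats into a
template: template power is "signal", the per-beat residual is "noise", and
the reported figure is the mean over beats of the per-beat dB ratio. This
tracks an additively constructed broadband SNR and degrades sharply when
beat detection itself breaks down, which is the failure the gate exists to
catch.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config as _cfg
from .peaks_ibi import IBISeries, PeakSeries, build_ibi, detect_beats
from .preprocess import FilterSpec, preprocess
from .signal_io import Recording

_SNR_CAP_DB = 80.0


@dataclass(frozen=True)
class QualityReport:
    valid_peak_fraction: float
    mean_snr_db: float
    passed: bool
    reasons: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        snr = self.mean_snr_db
        return {
            "valid_peak_fraction": self.valid_peak_fraction,
            "mean_snr_db": snr if np.isfinite(snr) else None,
            "passed": self.passed,
            "reasons": list(self.reasons),
        }


def valid_peak_fraction(ibi: IBISeries) -> float:
    """Fraction of intervals inside the physiological-bounds mask."""
    if len(ibi) == 0:
        raise ValueError("empty IBI series")
    return float(np.mean(ibi.valid))


def estimate_snr_db(rec: Recording, peaks: PeakSeries) -> float:
    """Mean over beats of 10*log10(template power / residual power).

    Beats are windows of 0.8x the median inter-beat gap centred on each
    detected peak; their ensemble average is the signal template. Windows
    clipped by the record edges are skipped. Returns -inf when fewer than
    three full beats are available.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks")
    x = rec.samples
    gaps = np.diff(peaks.indices)
    half = max(2, int(round(0.4 * float(np.median(gaps)))))
    beats = [
        x[p - half : p + half + 1]
        for p in peaks.indices
        if p - half >= 0 and p + half + 1 <= x.size
    ]
    if len(beats) < 3:
        return float("-inf")
    stack = np.vstack(beats)
    stack = stack - stack.mean(axis=1, keepdims=True)
    template = stack.mean(axis=0)
    p_sig = float(np.mean(template**2))
    if p_sig <= 0:
        return float("-inf")
    floor = p_sig * 10 ** (-_SNR_CAP_DB / 10)
    per_beat = [
        10 * np.log10(p_sig / max(float(np.mean((b - template) ** 2)), floor))
        for b in stack
    ]
    return float(np.mean(per_beat))


def quality_gate(
    rec: Recording,
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
    *,
    preprocessed: bool = False,
) -> QualityReport:
    """Run both quality checks on a segment and report the verdict.

    Always returns a report; an unprocessable segment (too few beats, flat
    signal) fails with an explanatory reason rather than raising.
    """
    spec = FilterSpec(
        sg_order=cfg.sg_order,
        sg_frames=cfg.sg_frames,
        bp_order=cfg.bp_order,
        bp_low=cfg.bp_low_hz,
        bp_high=cfg.bp_high_hz,
        norm_scale=cfg.norm_scale,
    )
    try:
        proc = rec if preprocessed else preprocess(rec, spec)
        peaks = detect_beats(proc, cfg)
        if len(peaks) < 2:
            return QualityReport(0.0, float("-inf"), False, ("too_few_peaks",))
        ibi = build_ibi(peaks, proc.n_samples, cfg.min_ibi_ms, cfg.max_ibi_ms)
    except ValueError as err:
        return QualityReport(0.0, float("-inf"), False, (str(err),))
    frac = valid_peak_fraction(ibi)
    # SNR is measured on the unconditioned signal: smoothing/band-passing
    # strips noise and would inflate the figure the gate screens on.
    snr = estimate_snr_db(rec, peaks)
    reasons = []
    if frac < cfg.gate_min_valid_fraction:
        reasons.append("valid_peak_fraction")
    if not snr > cfg.gate_min_snr_db:
        reasons.append("snr")
    return QualityReport(frac, snr, not reasons, tuple(reasons))
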