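"""Training-free AFIB detector from first-derivative spikes of the IBI series.

Atrial fibrillation produces an irregularly irregular beat sequence, so the
successive differences of the inter-beat intervals show frequent large
spikes. Per 8 s frame (2 s stride) we count differences whose magnitude
exceeds a spike threshold (default 50 ms) and divide by the number of beats
in the frame; a segment is called AFIB when the mean of this abnormal-change
ratio over all reliable frames exceeds a decision threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config as _cfg
from .peaks_ibi import IBISeries, ReliableFrame, build_ibi, detect_beats, find_reliable_frames
from .preprocess import FilterSpec, preprocess
from .signal_io import Recording, Rhythm


@dataclass(frozen=True)
class DSPFrameStat:
    start_s: float
    n_peaks: int
    n_spikes: int
    abnormal_ratio: float

    @property
    def has_abnormal(self) -> bool:
        return self.n_spikes > 0


@dataclass(frozen=True)
class DSPDecision:
    """Outcome of the spike-ratio method on one segment.

    ``label`` is ``None`` when no reliable frame was found (unclassifiable:
    distinct from both rhythm calls).
    """

    label: Rhythm | None
    mean_ratio: float
    frame_stats: tuple[DSPFrameStat, ...]
    spike_threshold_ms: float
    decision_threshold: float

    @property
    def unclassifiable(self) -> bool:
        return self.label is None

    def to_dict(self) -> dict:
        return {
            "label": self.label.value if self.label else "UNCLASSIFIABLE",
            "mean_ratio": self.mean_ratio,
            "n_frames": len(self.frame_stats),
            "spike_threshold_ms": self.spike_threshold_ms,
            "decision_threshold": self.decision_threshold,
            "frames": [
                {
                    "start_s": f.start_s,
                    "n_peaks": f.n_peaks,
                    "n_spikes": f.n_spikes,
                    "abnormal_ratio": f.abnormal_ratio,
                }
                for f in self.frame_stats
            ],
        }


def count_spikes(intervals_ms: np.ndarray, spike_threshold_ms: float) -> int:
    """Number of successive-interval differences strictly above threshold."""
    diffs = np.diff(np.asarray(intervals_ms, dtype=float))
    return int(np.sum(np.abs(diffs) > spike_threshold_ms))


def frame_spike_stats(
    frame: ReliableFrame,
    spike_threshold_ms: float = _cfg.DEFAULT_SPIKE_THRESHOLD_MS,
) -> DSPFrameStat:
    """Abnormal-change statistics of one frame.

    The first derivative is taken on the frame's per-gap interval sequence
    in ms (not on the sample-expanded trace, whose step edges would repeat
    each spike once per sample); the ratio divides spike count by the number
    of peaks in the frame.
    """
    if frame.n_peaks < 3:
        raise ValueError("need at least 3 peaks (2 intervals) in a frame")
    n_spikes = count_spikes(frame.intervals_ms(), spike_threshold_ms)
    return DSPFrameStat(
        start_s=frame.start_s,
        n_peaks=frame.n_peaks,
        n_spikes=n_spikes,
        abnormal_ratio=n_spikes / frame.n_peaks,
    )


def decide_from_ibi(
    ibi: IBISeries,
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
) -> DSPDecision:
    """Apply the frame sweep and mean-ratio decision to a built IBI series."""
    frames = find_reliable_frames(ibi, cfg.dsp_window_s, cfg.dsp_stride_s, min_peaks=3)
    stats = tuple(frame_spike_stats(f, cfg.spike_threshold_ms) for f in frames)
    if not stats:
        return DSPDecision(
            None, float("nan"), (), cfg.spike_threshold_ms, cfg.decision_threshold
        )
    mean_ratio = float(np.mean([s.abnormal_ratio for s in stats]))
    label = Rhythm.AFIB if mean_ratio > cfg.decision_threshold else Rhythm.NSR
    return DSPDecision(
        label, mean_ratio, stats, cfg.spike_threshold_ms, cfg.decision_threshold
    )


def classify_dsp(
    rec: Recording,
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
    *,
    preprocessed: bool = False,
) -> DSPDecision:
    """Full spike-ratio pipeline on a raw (or pre-conditioned) record."""
    spec = FilterSpec(
        sg_order=cfg.sg_order,
        sg_frames=cfg.sg_frames,
        bp_order=cfg.bp_order,
        bp_low=cfg.bp_low_hz,
        bp_high=cfg.bp_high_hz,
        norm_scale=cfg.norm_scale,
    )
    proc = rec if preprocessed else preprocess(rec, spec)
    peaks = detect_beats(proc, cfg)
    if len(peaks) < 2:
        return DSPDecision(
            None, float("nan"), (), cfg.spike_threshold_ms, cfg.decision_threshold
        )
    ibi = build_ibi(peaks, proc.n_samples, cfg.min_ibi_ms, cfg.max_ibi_ms)
    return decide_from_ibi(ibi, cfg)


def calibrate_decision_threshold(
    mean_ratios: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Youden-optimal decision threshold from labelled mean ratios.

    ``labels`` are truthy for AFIB. Candidate thresholds are midpoints of
    the sorted ratios; returns ``(threshold, J)`` with J = TPR - FPR,
    breaking ties toward the lower threshold (sensitivity-favouring).
    """
    r = np.asarray(mean_ratios, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if r.size != y.size or r.size < 2 or y.all() or not y.any():
        raise ValueError("need ratios with both classes present")
    order = np.sort(np.unique(r))
    cands = (order[:-1] + order[1:]) / 2.0
    best_t, best_j = float(cands[0]), -np.inf
    for t in cands:
        pred = r > t
        tpr = np.mean(pred[y])
        fpr = np.mean(pred[~y])
        j = tpr - fpr
        if j > best_j:
            best_t, best_j = float(t), float(j)
    return best_t, best_j
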