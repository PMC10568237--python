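"""Per-frame heart-rate-variability features.

Seven short-term HRV indices are computed per 15 s frame from the NN
intervals (the artifact-filtered inter-beat intervals, ms):

- HRMAD: mean absolute deviation of NN (default) or of the instantaneous
  heart rate 60000/NN in bpm (config switch)
- RMSSD: root mean square of successive NN differences
- IQRNN: inter-quartile range of NN (linear-interpolation quartiles)
- MCVNN: HRMAD / median(NN)
- CVNN: SD(NN) / mean(NN)  (sample SD, ddof=1)
- CVSD: RMSSD / mean(NN)
- HTI: HRV triangular index, count(NN) / modal histogram bin count with a
  fixed 1/128 s bin width aligned at zero
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config as _cfg
from .peaks_ibi import ReliableFrame, build_ibi, detect_beats, find_reliable_frames
from .preprocess import FilterSpec, preprocess
from .quality import quality_gate
from .signal_io import RhythmBlock

FEATURE_COLUMNS = ["hrmad", "rmssd", "iqrnn", "mcvnn", "cvnn", "cvsd", "hti"]

MIN_INTERVALS_PER_FRAME = 5


def hrv_triangular_index(nn_ms: np.ndarray, bin_ms: float = _cfg.DEFAULT_HTI_BIN_MS) -> float:
    """Total NN count divided by the modal bin height of the NN histogram."""
    nn = np.asarray(nn_ms, dtype=float)
    edges = np.arange(0.0, nn.max() + 2 * bin_ms, bin_ms)
    counts, _ = np.histogram(nn, bins=edges)
    return nn.size / counts.max()


def features_from_nn(
    nn_ms: np.ndarray,
    *,
    hrmad_on_bpm: bool = _cfg.DEFAULT_HRMAD_ON_BPM,
    hti_bin_ms: float = _cfg.DEFAULT_HTI_BIN_MS,
) -> dict[str, float]:
    """The seven features from a bare NN vector (ms)."""
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < MIN_INTERVALS_PER_FRAME:
        raise ValueError(f"need at least {MIN_INTERVALS_PER_FRAME} intervals")
    if np.any(nn <= 0) or not np.all(np.isfinite(nn)):
        raise ValueError("NN intervals must be finite and positive")
    mean = float(nn.mean())
    median = float(np.median(nn))
    rmssd = float(math.sqrt(np.mean(np.diff(nn) ** 2)))
    q1, q3 = np.percentile(nn, [25, 75])
    base = 60000.0 / nn if hrmad_on_bpm else nn
    hrmad = float(np.mean(np.abs(base - base.mean())))
    return {
        "hrmad": hrmad,
        "rmssd": rmssd,
        "iqrnn": float(q3 - q1),
        "mcvnn": hrmad / median,
        "cvnn": float(nn.std(ddof=1)) / mean,
        "cvsd": rmssd / mean,
        "hti": hrv_triangular_index(nn, hti_bin_ms),
    }


def compute_features(
    frame: ReliableFrame,
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
) -> dict[str, float]:
    """Feature row for one reliable frame (its intervals are all valid NN)."""
    return features_from_nn(
        frame.intervals_ms(),
        hrmad_on_bpm=cfg.hrmad_on_bpm,
        hti_bin_ms=cfg.hti_bin_ms,
    )


def extract_dataset(
    blocks: list[RhythmBlock],
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
    *,
    window_s: float | None = None,
    stride_s: float | None = None,
    apply_gate: bool = False,
) -> pd.DataFrame:
    """Sliding-window feature table over rhythm blocks.

    One row per reliable frame per block, in deterministic
    (block, frame-start) order, with the block's label and subject carried
    along. Blocks that fail preprocessing, beat detection or (optionally)
    the quality gate contribute no rows.
    """
    window_s = cfg.ml_window_s if window_s is None else window_s
    stride_s = cfg.ml_stride_s if stride_s is None else stride_s
    spec = FilterSpec(
        sg_order=cfg.sg_order,
        sg_frames=cfg.sg_frames,
        bp_order=cfg.bp_order,
        bp_low=cfg.bp_low_hz,
        bp_high=cfg.bp_high_hz,
        norm_scale=cfg.norm_scale,
    )
    rows = []
    for block in blocks:
        rec = block.recording
        if apply_gate and not quality_gate(rec, cfg).passed:
            continue
        try:
            proc = preprocess(rec, spec)
            peaks = detect_beats(proc, cfg)
            if len(peaks) < MIN_INTERVALS_PER_FRAME + 1:
                continue
            ibi = build_ibi(peaks, proc.n_samples, cfg.min_ibi_ms, cfg.max_ibi_ms)
        except ValueError:
            continue
        frames = find_reliable_frames(
            ibi, window_s, stride_s, min_peaks=MIN_INTERVALS_PER_FRAME + 1
        )
        for frame in frames:
            row = compute_features(frame, cfg)
            row["label"] = block.label.value
            row["subject_id"] = rec.subject_id
            row["block_id"] = rec.record_id
            row["frame_start_s"] = frame.start_s
            rows.append(row)
    cols = FEATURE_COLUMNS + ["label", "subject_id", "block_id", "frame_start_s"]
    return pd.DataFrame(rows, columns=cols)
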