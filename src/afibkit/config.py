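"""Pipeline configuration.

Every tunable constant of the screening pipeline lives here with its default,
so a run is fully described by one :class:`PipelineConfig`. Defaults follow
the published processing chain (Savitzky-Golay order 4 / 19 frames, 2nd-order
Butterworth 0.5-20 Hz band-pass, min-max scale 10, 8 s / 2 s DSP windows,
15 s / 2 s HRV windows, 50 ms spike threshold, 75% valid-peak and 5 dB
quality gates); values the source method leaves unstated (IBI validity
bounds, the mean-ratio decision threshold, model hyper-parameters) carry the
package's documented defaults and are equally overridable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

try:  # py311+
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None

# Waveform conditioning
DEFAULT_SG_ORDER = 4
DEFAULT_SG_FRAMES = 19
DEFAULT_BP_ORDER = 2
DEFAULT_BP_LOW_HZ = 0.5
DEFAULT_BP_HIGH_HZ = 20.0
DEFAULT_NORM_SCALE = 10.0

# Beat detection
DEFAULT_PEAK_REFRACTORY_S = 0.27
DEFAULT_PEAK_THRESHOLD_FRAC = 0.5
DEFAULT_PEAK_PERCENTILE = 99.5
DEFAULT_PEAK_BLOCK_S = 2.0
DEFAULT_PEAK_FLOOR_FRAC = 0.25
DEFAULT_DOUBLE_PEAK_MIN_SEP_MS = 250.0

# IBI validity mask (physiological bounds, ~40-220 bpm)
DEFAULT_MIN_IBI_MS = 270.0
DEFAULT_MAX_IBI_MS = 1500.0

# DSP (spike-ratio) detector
DEFAULT_DSP_WINDOW_S = 8.0
DEFAULT_DSP_STRIDE_S = 2.0
DEFAULT_SPIKE_THRESHOLD_MS = 50.0
DEFAULT_DECISION_THRESHOLD = 0.15

# HRV feature extraction
DEFAULT_ML_WINDOW_S = 15.0
DEFAULT_ML_STRIDE_S = 2.0
DEFAULT_HTI_BIN_MS = 1000.0 / 128.0  # conventional 1/128 s histogram bin
DEFAULT_HRMAD_ON_BPM = False

# Signal-quality gate
DEFAULT_GATE_MIN_VALID_FRACTION = 0.75
DEFAULT_GATE_MIN_SNR_DB = 5.0

# Classifier training
DEFAULT_SPLIT_FRACTION = 0.6
DEFAULT_RF_N_ESTIMATORS = 300
DEFAULT_SVM_C = 1.0
DEFAULT_KNN_K = 15


@dataclass(frozen=True)
class PipelineConfig:
    sg_order: int = DEFAULT_SG_ORDER
    sg_frames: int = DEFAULT_SG_FRAMES
    bp_order: int = DEFAULT_BP_ORDER
    bp_low_hz: float = DEFAULT_BP_LOW_HZ
    bp_high_hz: float = DEFAULT_BP_HIGH_HZ
    norm_scale: float = DEFAULT_NORM_SCALE

    peak_refractory_s: float = DEFAULT_PEAK_REFRACTORY_S
    peak_threshold_frac: float = DEFAULT_PEAK_THRESHOLD_FRAC
    peak_percentile: float = DEFAULT_PEAK_PERCENTILE
    peak_block_s: float = DEFAULT_PEAK_BLOCK_S
    peak_floor_frac: float = DEFAULT_PEAK_FLOOR_FRAC
    double_peak_min_sep_ms: float = DEFAULT_DOUBLE_PEAK_MIN_SEP_MS

    min_ibi_ms: float = DEFAULT_MIN_IBI_MS
    max_ibi_ms: float = DEFAULT_MAX_IBI_MS

    dsp_window_s: float = DEFAULT_DSP_WINDOW_S
    dsp_stride_s: float = DEFAULT_DSP_STRIDE_S
    spike_threshold_ms: float = DEFAULT_SPIKE_THRESHOLD_MS
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD

    ml_window_s: float = DEFAULT_ML_WINDOW_S
    ml_stride_s: float = DEFAULT_ML_STRIDE_S
    hti_bin_ms: float = DEFAULT_HTI_BIN_MS
    hrmad_on_bpm: bool = DEFAULT_HRMAD_ON_BPM

    gate_min_valid_fraction: float = DEFAULT_GATE_MIN_VALID_FRACTION
    gate_min_snr_db: float = DEFAULT_GATE_MIN_SNR_DB

    split_fraction: float = DEFAULT_SPLIT_FRACTION
    rf_n_estimators: int = DEFAULT_RF_N_ESTIMATORS
    svm_c: float = DEFAULT_SVM_C
    knn_k: int = DEFAULT_KNN_K

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML config; unknown keys are rejected."""
    if tomllib is None:  # pragma: no cover
        raise RuntimeError("TOML support requires Python >= 3.11")
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
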