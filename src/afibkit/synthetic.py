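"""Synthetic NSR/AFIB beat sequences, waveforms and cohorts.

The generator emulates the rhythm classes the detectors discriminate:

- NSR: inter-beat intervals around a mean with mild respiratory sinus
  arrhythmia (a slow sinusoidal modulation) plus small Gaussian jitter.
- AFIB: intervals drawn i.i.d. from a right-shifted Gamma matched to a
  target mean and standard deviation - serially uncorrelated, the operative
  signature of fibrillation at the beat-stream level.
- Optional ectopy: isolated premature-beat motifs replacing (rr_i, rr_i+1)
  with (0.6*rr_i, 1.4*rr_i+1), a short beat followed by a compensatory
  pause.

Waveform rendering places a narrow Gaussian R-spike (ECG) or an asymmetric
gamma-shaped pulse (PPG) at each beat and can add white noise at a target
SNR; ground-truth peak positions are returned alongside. All randomness is
driven by the :class:`SyntheticSpec` seed through per-stage substreams.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import config as _cfg
from .signal_io import Modality, Recording, Rhythm, RhythmBlock

# Cohort hyper-ranges: per-subject parameters are drawn uniformly from these.
NSR_MEAN_RR_RANGE = (700.0, 1000.0)
NSR_JITTER_RANGE = (15.0, 30.0)
NSR_RSA_DEPTH_RANGE = (10.0, 25.0)
NSR_RSA_FREQ_RANGE = (0.2, 0.3)
NSR_ECTOPIC_RATE_RANGE = (0.0, 1.0)
AFIB_MEAN_RR_RANGE = (550.0, 850.0)
AFIB_SIGMA_RANGE = (100.0, 200.0)

_AFIB_RR_SHIFT_MS = 250.0  # physiological floor of AV-node conduction


@dataclass(frozen=True)
class SyntheticSpec:
    rhythm: Rhythm = Rhythm.NSR
    duration_s: float = 60.0
    fs: float = 250.0
    modality: Modality = Modality.ECG
    mean_rr_ms: float = 800.0
    rr_jitter_ms: float = 20.0  # NSR beat-to-beat Gaussian jitter
    rr_sigma_ms: float = 150.0  # AFIB interval SD
    rsa_depth_ms: float = 20.0
    rsa_freq_hz: float = 0.25
    ectopic_rate_per_min: float = 0.0
    noise_snr_db: float | None = None  # None = noiseless
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not (_cfg.DEFAULT_MIN_IBI_MS <= self.mean_rr_ms <= _cfg.DEFAULT_MAX_IBI_MS):
            raise ValueError("mean_rr_ms outside physiological bounds")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        object.__setattr__(self, "rhythm", Rhythm(self.rhythm))
        object.__setattr__(self, "modality", Modality(self.modality))


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def generate_rr(spec: SyntheticSpec) -> np.ndarray:
    """Generate the RR interval sequence (ms) for one subject/segment.

    The sequence covers ``duration_s`` (cumulative time of the beat train,
    with a short lead-in margin at both ends for waveform rendering);
    intervals are clipped to the physiological bounds.
    """
    rng = _rng(spec, 0)
    budget_ms = spec.duration_s * 1000.0
    n = int(math.ceil(budget_ms / spec.mean_rr_ms)) + 8
    if spec.rhythm is Rhythm.NSR:
        t = np.arange(n) * spec.mean_rr_ms / 1000.0  # approximate beat times
        rr = (
            spec.mean_rr_ms
            + spec.rsa_depth_ms * np.sin(2 * np.pi * spec.rsa_freq_hz * t)
            + rng.normal(0.0, spec.rr_jitter_ms, n)
        )
    else:
        shift = min(_AFIB_RR_SHIFT_MS, spec.mean_rr_ms - 50.0)
        mu = spec.mean_rr_ms - shift
        k = (mu / spec.rr_sigma_ms) ** 2
        theta = spec.rr_sigma_ms**2 / mu
        rr = shift + rng.gamma(k, theta, n)
    rr = np.clip(rr, _cfg.DEFAULT_MIN_IBI_MS, _cfg.DEFAULT_MAX_IBI_MS)

    n_ect = rng.poisson(spec.ectopic_rate_per_min * spec.duration_s / 60.0)
    if n_ect > 0 and rr.size > 3:
        slots = rng.choice(np.arange(1, rr.size - 2), size=min(n_ect, rr.size // 4),
                           replace=False)
        for i in np.sort(slots):
            rr[i] *= 0.6
            rr[i + 1] *= 1.4

    # trim so the beat train (with rendering margin) fits the duration
    margin_ms = 600.0
    keep = np.searchsorted(np.cumsum(rr), budget_ms - 2 * margin_ms, side="right")
    return rr[: max(keep, 2)].copy()


def _ppg_kernel(fs: float) -> tuple[np.ndarray, int]:
    """Asymmetric gamma-shaped pulse; returns (kernel, index of its peak)."""
    tr, p = 0.18, 3.0
    t = np.arange(0.0, 1.2, 1.0 / fs)
    k = (t / tr) ** p * np.exp(p * (1.0 - t / tr))
    return k, int(np.argmax(k))


def render_waveform(
    rr_ms: np.ndarray, spec: SyntheticSpec
) -> tuple[Recording, np.ndarray]:
    """Render a beat train to a waveform; returns (recording, truth peaks).

    ECG beats are narrow Gaussian R-spikes (sigma 12 ms); PPG beats are
    asymmetric gamma-shaped pulses. White noise is added at
    ``spec.noise_snr_db`` relative to the clean waveform's variance.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size == 0:
        raise ValueError("empty RR sequence")
    lead_s = 0.5
    beat_times = lead_s + np.concatenate(([0.0], np.cumsum(rr))) / 1000.0
    n = int(round(spec.duration_s * spec.fs))
    n = max(n, int(math.ceil((beat_times[-1] + lead_s) * spec.fs)))
    x = np.zeros(n)
    truth = np.round(beat_times * spec.fs).astype(np.int64)
    truth = truth[truth < n]
    if spec.modality is Modality.ECG:
        sigma = 0.012 * spec.fs  # samples
        halfw = int(math.ceil(4 * sigma))
        kern = np.exp(-0.5 * ((np.arange(-halfw, halfw + 1)) / sigma) ** 2)
        peak_off = halfw
    else:
        kern, peak_off = _ppg_kernel(spec.fs)
    for p in truth:
        start = p - peak_off
        k0 = max(0, -start)
        k1 = min(kern.size, n - start)
        if k1 > k0:
            x[start + k0 : start + k1] += kern[k0:k1]
    if spec.noise_snr_db is not None and np.isfinite(spec.noise_snr_db):
        noise_rng = _rng(spec, 1)
        sigma_n = math.sqrt(float(np.var(x)) * 10 ** (-spec.noise_snr_db / 10.0))
        x = x + noise_rng.normal(0.0, sigma_n, n)
    rec = Recording(
        samples=x,
        fs=spec.fs,
        modality=spec.modality,
        subject_id=f"synth{spec.seed}",
        record_id=f"synth{spec.seed}-{spec.rhythm.value.lower()}",
    )
    return rec, truth


def synthesize_recording(spec: SyntheticSpec) -> tuple[Recording, np.ndarray]:
    """RR generation plus rendering in one call."""
    return render_waveform(generate_rr(spec), spec)


def make_cohort(
    n_subjects: int,
    prevalence: float = 0.5,
    seed: int = 0,
    *,
    duration_s: float = 60.0,
    fs: float = 250.0,
    modality: Modality | str = Modality.ECG,
    noise_snr_db: float | None = 25.0,
) -> tuple[list[RhythmBlock], pd.DataFrame]:
    """Deterministic synthetic cohort with per-subject parameter draws.

    Exactly ``round(n_subjects * prevalence)`` subjects are AFIB; subject
    parameters are drawn uniformly from the module's hyper-ranges. Returns
    the blocks and a truth table (one row per subject).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    n_afib = int(round(n_subjects * prevalence))
    base = [Rhythm.AFIB] * n_afib + [Rhythm.NSR] * (n_subjects - n_afib)
    labels = [base[i] for i in rng.permutation(n_subjects)]
    blocks: list[RhythmBlock] = []
    truth_rows = []
    for i, label in enumerate(labels):
        sub_seed = int(rng.integers(2**31 - 1))
        if label is Rhythm.NSR:
            params = dict(
                mean_rr_ms=rng.uniform(*NSR_MEAN_RR_RANGE),
                rr_jitter_ms=rng.uniform(*NSR_JITTER_RANGE),
                rsa_depth_ms=rng.uniform(*NSR_RSA_DEPTH_RANGE),
                rsa_freq_hz=rng.uniform(*NSR_RSA_FREQ_RANGE),
                ectopic_rate_per_min=rng.uniform(*NSR_ECTOPIC_RATE_RANGE),
            )
        else:
            params = dict(
                mean_rr_ms=rng.uniform(*AFIB_MEAN_RR_RANGE),
                rr_sigma_ms=rng.uniform(*AFIB_SIGMA_RANGE),
                rsa_depth_ms=0.0,
                ectopic_rate_per_min=0.0,
            )
        spec = SyntheticSpec(
            rhythm=label,
            duration_s=duration_s,
            fs=fs,
            modality=Modality(modality),
            noise_snr_db=noise_snr_db,
            seed=sub_seed,
            **params,
        )
        rec, _ = synthesize_recording(spec)
        subject = f"S{i:03d}"
        rec.subject_id = subject
        rec.record_id = f"{subject}-b0"
        blocks.append(
            RhythmBlock(
                recording=rec,
                label=label,
                source_record=subject,
                source_interval=(0, rec.n_samples),
            )
        )
        truth_rows.append(
            {
                "subject_id": subject,
                "block_id": rec.record_id,
                "label": label.value,
                "seed": sub_seed,
                **{k: float(v) for k, v in params.items()},
            }
        )
    return blocks, pd.DataFrame(truth_rows)
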