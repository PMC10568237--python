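"""Waveform record I/O, rhythm annotations and record slicing.

Records are single-channel ECG or PPG traces. Supported on-disk forms are
plain CSV (either ``time,amplitude`` or a bare amplitude column plus an
explicit sampling rate) and WFDB header/signal pairs (formats 16 and 212,
first channel). Rhythm annotations are half-open, 0-based sample intervals
and can be read from ``start,end,label`` CSV.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import resample_poly


class Modality(str, Enum):
    ECG = "ECG"
    PPG = "PPG"


class Rhythm(str, Enum):
    NSR = "NSR"
    AFIB = "AFIB"
    OTHER = "OTHER"


@dataclass
class Recording:
    """A uniformly sampled physiological waveform.

    ``subject_id`` must be non-empty: subject-wise train/test splitting
    depends on it.
    """

    samples: np.ndarray
    fs: float
    modality: Modality = Modality.ECG
    subject_id: str = "anon"
    record_id: str = "rec"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("no samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        self.modality = Modality(self.modality)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class RhythmAnnotation:
    """Sorted, non-overlapping half-open ``[start, end)`` rhythm intervals."""

    intervals: tuple[tuple[int, int, Rhythm], ...]

    def __post_init__(self):
        norm = tuple(
            (int(s), int(e), Rhythm(lab)) for s, e, lab in self.intervals
        )
        prev_end = 0
        for s, e, _ in norm:
            if s < 0 or e <= s:
                raise ValueError(f"bad interval [{s}, {e})")
            if s < prev_end:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = e
        object.__setattr__(self, "intervals", norm)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RhythmAnnotation":
        rows = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or not row[0].strip().lstrip("-").isdigit():
                    continue  # header or blank
                rows.append((int(row[0]), int(row[1]), Rhythm(row[2].strip())))
        return cls(tuple(rows))


@dataclass
class RhythmBlock:
    """A contiguous single-rhythm slice treated as an independent sample."""

    recording: Recording
    label: Rhythm
    source_record: str = ""
    source_interval: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.label = Rhythm(self.label)
        if self.label is Rhythm.OTHER:
            raise ValueError("blocks carry NSR or AFIB labels only")


# ---------------------------------------------------------------------------
# readers


def _infer_fs_from_times(times: np.ndarray) -> float:
    dt = np.median(np.diff(times))
    if dt <= 0:
        raise ValueError("time column is not increasing")
    return 1.0 / float(dt)


def _read_csv(path: Path, fs_override: float | None) -> tuple[np.ndarray, float]:
    raw = path.read_text()
    rows: list[list[str]] = []
    for line in raw.splitlines():
        line = line.strip()
        if not line:
            continue
        rows.append([c.strip() for c in line.split(",")])
    if rows:
        try:
            float(rows[0][0])
        except ValueError:
            rows = rows[1:]  # drop header
    if not rows:
        raise ValueError("no samples")
    ncol = len(rows[0])
    data = np.array([[float(c) for c in r] for r in rows])
    if ncol == 1:
        if fs_override is None:
            raise ValueError("single-column CSV requires fs_override")
        return data[:, 0], float(fs_override)
    times, amps = data[:, 0], data[:, 1]
    fs = float(fs_override) if fs_override else _infer_fs_from_times(times)
    return amps, fs


def _parse_wfdb_header(text: str) -> tuple[dict, list[dict]]:
    lines = [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    rec = {
        "name": head[0].split("/")[0],
        "nsig": int(head[1]),
        "fs": float(head[2].split("/")[0]) if len(head) > 2 else 250.0,
        "nsamp": int(head[3]) if len(head) > 3 else 0,
    }
    sigs = []
    for ln in lines[1 : 1 + rec["nsig"]]:
        parts = ln.split()
        fmt = parts[1]
        for sep in ("x", ":", "+"):
            fmt = fmt.split(sep)[0]
        sigs.append({"file": parts[0], "fmt": int(fmt)})
    return rec, sigs


def _decode_212(buf: bytes) -> np.ndarray:
    b = np.frombuffer(buf, dtype=np.uint8)
    b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * len(b), dtype=np.int32)
    out[0::2], out[1::2] = s0, s1
    out[out > 2047] -= 4096
    return out


def _read_wfdb(path: Path, channel: int = 0) -> tuple[np.ndarray, float]:
    rec, sigs = _parse_wfdb_header(path.read_text())
    nsig = rec["nsig"]
    if not (0 <= channel < nsig):
        raise ValueError(f"channel {channel} not in record ({nsig} signals)")
    fmt = sigs[channel]["fmt"]
    dat = path.with_name(sigs[channel]["file"])
    buf = dat.read_bytes()
    if fmt == 16:
        flat = np.frombuffer(buf, dtype="<i2").astype(np.int32)
    elif fmt == 212:
        flat = _decode_212(buf)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    flat = flat[: (len(flat) // nsig) * nsig]
    sig = flat.reshape(-1, nsig)[:, channel]
    if rec["nsamp"]:
        sig = sig[: rec["nsamp"]]
    if sig.size == 0:
        raise ValueError("no samples")
    return sig.astype(float), rec["fs"]


def read_record(
    path: str | Path,
    modality: Modality | str = Modality.ECG,
    fs_override: float | None = None,
    subject_id: str | None = None,
    channel: int = 0,
) -> Recording:
    """Read a waveform record from CSV or a WFDB header file.

    Amplitudes are passed through unscaled (raw ADC units for WFDB).
    CSV may be ``time,amplitude`` (fs inferred from the median time step)
    or a single amplitude column, which requires ``fs_override``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".hea":
        samples, fs = _read_wfdb(path, channel)
    else:
        samples, fs = _read_csv(path, fs_override)
    name = path.stem
    return Recording(
        samples=samples,
        fs=fs,
        modality=Modality(modality),
        subject_id=subject_id or name,
        record_id=name,
    )


def write_record_csv(rec: Recording, path: str | Path, with_time: bool = True) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if with_time:
            w.writerow(["time_s", "amplitude"])
            for i, v in enumerate(rec.samples):
                w.writerow([f"{i / rec.fs:.6f}", f"{v:.8g}"])
        else:
            w.writerow(["amplitude"])
            for v in rec.samples:
                w.writerow([f"{v:.8g}"])


# ---------------------------------------------------------------------------
# slicing


def split_by_rhythm(
    rec: Recording,
    ann: RhythmAnnotation,
    keep: Iterable[Rhythm | str] = (Rhythm.NSR, Rhythm.AFIB),
) -> list[RhythmBlock]:
    """Cut a long record into per-rhythm blocks treated as independent samples.

    ``OTHER`` intervals (and any label not in ``keep``) are dropped; kept
    blocks appear in record order with their labels preserved.
    """
    keep_set = {Rhythm(k) for k in keep}
    blocks: list[RhythmBlock] = []
    for i, (start, end, label) in enumerate(ann.intervals):
        if end > rec.n_samples:
            raise ValueError(
                f"interval [{start}, {end}) exceeds record length {rec.n_samples}"
            )
        if label not in keep_set or label is Rhythm.OTHER:
            continue
        sub = Recording(
            samples=rec.samples[start:end].copy(),
            fs=rec.fs,
            modality=rec.modality,
            subject_id=rec.subject_id,
            record_id=f"{rec.record_id}-b{i}",
        )
        blocks.append(
            RhythmBlock(
                recording=sub,
                label=label,
                source_record=rec.record_id,
                source_interval=(start, end),
            )
        )
    return blocks


def segment_fixed(
    rec: Recording, window_s: float, overlap_s: float = 0.0
) -> list[Recording]:
    """Cut a record into fixed windows; the final partial window is dropped."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not (0 <= overlap_s < window_s):
        raise ValueError("need 0 <= overlap_s < window_s")
    win = int(round(window_s * rec.fs))
    step = win - int(round(overlap_s * rec.fs))
    out = []
    for k, start in enumerate(range(0, rec.n_samples - win + 1, step)):
        out.append(
            Recording(
                samples=rec.samples[start : start + win].copy(),
                fs=rec.fs,
                modality=rec.modality,
                subject_id=rec.subject_id,
                record_id=f"{rec.record_id}-s{k}",
            )
        )
    return out


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs``."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > rec.fs:
        raise ValueError("target_fs exceeds record rate")
    if target_fs == rec.fs:
        return replace(rec, samples=rec.samples.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    # high-beta Kaiser keeps passband error well below waveform quantization
    y = resample_poly(
        rec.samples, frac.numerator, frac.denominator, window=("kaiser", 14.0)
    )
    return Recording(
        samples=y,
        fs=rec.fs * frac.numerator / frac.denominator,
        modality=rec.modality,
        subject_id=rec.subject_id,
        record_id=rec.record_id,
    )
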