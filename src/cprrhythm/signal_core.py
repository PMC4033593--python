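"""Signal containers, CSV I/O and preprocessing shared by every stage.

The analysis chain operates on ECG (mV) and compression-depth (mm) traces
sampled at a common rate.  All downstream processing assumes the AED-style
preprocessing implemented here: resampling to 250 Hz, causal 0.5-30 Hz
order-10 Butterworth band-pass, and segmentation into non-overlapping 9-s
analysis segments of three 3-s windows each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

#: working sampling rate of the whole analysis chain (Hz)
DEFAULT_FS = 250.0
#: ECG monitor band (Hz) used by the band-pass preprocessing
ECG_BAND = (0.5, 30.0)
#: analysis window length (s) and windows per diagnostic segment
WINDOW_S = 3.0
SEGMENT_WINDOWS = 3

RHYTHM_LABELS = {"VF", "VT", "ASY", "PEA", "PR", "ORG", "unknown"}
SHOCKABLE_LABELS = {"VF", "VT"}


class FormatError(ValueError):
    """A record file is malformed or uses an unsupported layout."""


class ValidationError(ValueError):
    """A signal container violates one of its invariants."""


@dataclass
class SignalTrace:
    """A uniformly sampled scalar trace (ECG in mV, compression depth in mm)."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("trace contains non-finite samples")
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Covered time span in seconds (n samples at fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.fs


@dataclass
class CCMarks:
    """Chest-compression instants t_k in seconds, strictly increasing."""

    t_k: np.ndarray

    def __post_init__(self) -> None:
        self.t_k = np.asarray(self.t_k, dtype=float).ravel()
        if self.t_k.size and not np.all(np.isfinite(self.t_k)):
            raise ValidationError("compression marks contain non-finite values")
        if self.t_k.size and self.t_k[0] < 0:
            raise ValidationError("compression marks must be non-negative")
        if self.t_k.size > 1 and not np.all(np.diff(self.t_k) > 0):
            raise ValidationError("compression marks must be strictly increasing")

    @property
    def n(self) -> int:
        return self.t_k.size

    def validate_rates(self, min_period: float = 0.2, max_period: float = 2.0) -> None:
        """Check inter-compression intervals against physiologic limits."""
        if self.n < 2:
            return
        d = np.diff(self.t_k)
        if np.any(d <= min_period) or np.any(d >= max_period):
            bad = d[(d <= min_period) | (d >= max_period)][0]
            raise ValidationError(
                f"inter-compression interval {bad:.3f} s outside ({min_period}, {max_period}) s"
            )


@dataclass
class SignalRecord:
    """One analysis record: ECG, optional depth channel, marks and metadata.

    ``clean`` and ``artifact`` hold the noise-free rhythm and the pure
    compression artifact when the record was synthesized, so filter output can
    be scored against ground truth; for real recordings they are ``None``.
    """

    ecg: SignalTrace
    cc_marks: CCMarks = field(default_factory=lambda: CCMarks(np.empty(0)))
    cd: Optional[SignalTrace] = None
    rhythm_label: str = "unknown"
    patient_id: str = ""
    record_id: str = ""
    clean: Optional[SignalTrace] = None
    artifact: Optional[SignalTrace] = None

    def __post_init__(self) -> None:
        if self.rhythm_label not in RHYTHM_LABELS:
            raise ValidationError(f"unknown rhythm label {self.rhythm_label!r}")
        if self.cd is not None:
            if abs(self.cd.duration - self.ecg.duration) > 1.0 / min(self.ecg.fs, self.cd.fs):
                raise ValidationError("ECG and CD traces must cover the same time span")
        if self.cc_marks.n:
            t0 = self.ecg.start_time
            t1 = t0 + self.ecg.duration
            if self.cc_marks.t_k[0] < t0 - 1e-9 or self.cc_marks.t_k[-1] > t1 + 1e-9:
                raise ValidationError("compression marks fall outside the record time span")

    @property
    def is_shockable(self) -> bool:
        return self.rhythm_label in SHOCKABLE_LABELS


@dataclass
class AnalysisSegment:
    """Three contiguous 3-s windows forming one 9-s diagnostic unit."""

    windows: np.ndarray  # shape (3, window_samples)
    fs: float
    start_index: int = 0
    segment_label: Optional[str] = None  # "Sh" / "NSh" when ground truth is known

    def __post_init__(self) -> None:
        expected = int(round(WINDOW_S * self.fs))
        if self.windows.shape != (SEGMENT_WINDOWS, expected):
            raise ValidationError(
                f"segment must be {SEGMENT_WINDOWS} windows of {expected} samples, "
                f"got shape {self.windows.shape}"
            )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("time", "ecg_mv", "cd_mm")


def read_record(
    path: str | Path,
    format: str = "csv",
    marks_path: str | Path | None = None,
    rhythm_label: str = "unknown",
) -> SignalRecord:
    """Read a record from disk.

    CSV dialect: header ``time,ecg_mv[,cd_mm]`` with a uniform time column in
    seconds.  Compression marks are read from ``marks_path`` (one t_k per
    line, seconds) when given, otherwise left empty.
    """
    if format == "wfdb":
        raise FormatError(
            "WFDB input requires the 'wfdb' package, which is not installed; "
            "convert the record to the CSV dialect (time,ecg_mv,cd_mm)"
        )
    if format != "csv":
        raise FormatError(f"unsupported format {format!r}")
    path = Path(path)
    df = pd.read_csv(path)
    if "ecg_mv" not in df.columns:
        raise FormatError(f"{path}: missing required 'ecg_mv' channel")
    if "time" not in df.columns:
        raise FormatError(f"{path}: missing 'time' column (needed to infer sampling rate)")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples to infer sampling rate")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise FormatError(f"{path}: time column is not increasing")
    fs = 1.0 / dt
    ecg = SignalTrace(df["ecg_mv"].to_numpy(dtype=float), fs=fs, start_time=float(t[0]))
    cd = None
    if "cd_mm" in df.columns:
        cd = SignalTrace(df["cd_mm"].to_numpy(dtype=float), fs=fs, start_time=float(t[0]))
    marks = CCMarks(np.empty(0))
    if marks_path is not None:
        raw = np.loadtxt(marks_path, dtype=float, ndmin=1)
        marks = CCMarks(raw)
    return SignalRecord(
        ecg=ecg, cd=cd, cc_marks=marks, rhythm_label=rhythm_label, record_id=path.stem
    )


def write_record(
    record: SignalRecord, path: str | Path, marks_path: str | Path | None = None
) -> None:
    """Write a record in the CSV dialect used by :func:`read_record`."""
    path = Path(path)
    data = {"time": record.ecg.times, "ecg_mv": record.ecg.samples}
    if record.cd is not None:
        data["cd_mm"] = record.cd.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    if marks_path is not None:
        np.savetxt(marks_path, record.cc_marks.t_k, fmt="%.9g")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def resample_to_fs(trace: SignalTrace, target_fs: float = DEFAULT_FS) -> SignalTrace:
    """Rational polyphase resampling with anti-alias filtering.

    Exact for integer-ratio cases such as the common 500 -> 250 Hz decimation.
    """
    if not (target_fs > 0):
        raise ValidationError("target sampling rate must be positive")
    if math.isclose(trace.fs, target_fs, rel_tol=1e-9):
        return trace
    frac = Fraction(target_fs / trace.fs).limit_denominator(10_000)
    out = sps.resample_poly(trace.samples, frac.numerator, frac.denominator)
    return SignalTrace(out, fs=target_fs, start_time=trace.start_time)


@lru_cache(maxsize=8)
def _bandpass_sos(fs: float, lo: float, hi: float, order: int) -> np.ndarray:
    return sps.butter(order // 2, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_ecg(
    trace: SignalTrace, band: tuple[float, float] = ECG_BAND, order: int = 10
) -> SignalTrace:
    """Causal order-10 Butterworth band-pass, the AED monitor bandwidth.

    Applied causally (second-order sections) because a streaming device cannot
    look ahead; the group delay is a few tens of milliseconds and affects all
    rhythm classes alike.
    """
    if not math.isclose(trace.fs, DEFAULT_FS, rel_tol=1e-9):
        raise ValidationError(
            f"band-pass expects the working rate {DEFAULT_FS} Hz, got {trace.fs}"
        )
    sos = _bandpass_sos(trace.fs, band[0], band[1], order)
    out = sps.sosfilt(sos, trace.samples)
    return SignalTrace(out, fs=trace.fs, start_time=trace.start_time)


def segment_windows(x: np.ndarray, fs: float) -> np.ndarray:
    """Reshape a 1-D signal into (n_segments, 3, window_samples), dropping the tail."""
    w = int(round(WINDOW_S * fs))
    seg_len = SEGMENT_WINDOWS * w
    n_seg = len(x) // seg_len
    return x[: n_seg * seg_len].reshape(n_seg, SEGMENT_WINDOWS, w)


def extract_segments(record: SignalRecord) -> list[AnalysisSegment]:
    """Split a preprocessed record into non-overlapping 9-s analysis segments.

    Windows are aligned to sample 0 of the record; the trailing remainder
    shorter than 9 s is dropped.
    """
    fs = record.ecg.fs
    stacked = segment_windows(record.ecg.samples, fs)
    label = None
    if record.rhythm_label != "unknown":
        label = "Sh" if record.is_shockable else "NSh"
    seg_len = stacked.shape[1] * stacked.shape[2] if stacked.size else 0
    return [
        AnalysisSegment(windows=stacked[i], fs=fs, start_index=i * seg_len, segment_label=label)
        for i in range(stacked.shape[0])
    ]


def marks_from_depth(cd: SignalTrace, min_depth: float = 10.0, refractory_s: float = 0.2) -> CCMarks:
    """Re-detect compression instants from the depth channel.

    Peak detection with a physiologic refractory period; ``min_depth`` (mm)
    rejects baseline ripple between compression episodes.
    """
    distance = max(1, int(round(refractory_s * cd.fs)))
    idx, _ = sps.find_peaks(cd.samples, height=min_depth, distance=distance)
    return CCMarks(cd.start_time + idx / cd.fs)
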