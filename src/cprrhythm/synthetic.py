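"""Seedable generators for rhythms, compression artifacts and mixed corpora.

Clean rhythm classes mimic the coarse electrophysiological signatures the
downstream features rely on rather than a full cardiac model:

* coarse VF — narrow-band filtered Gaussian noise around the fibrillation
  frequency with slow amplitude modulation, scaled to a target peak-to-peak
  amplitude above 0.2 mV;
* ORG — a periodic train of sharp biphasic QRS-like deflections (~100 ms)
  with a small T-wave hump and low-amplitude baseline noise;
* ASY — low-pass noise capped below 0.1 mV peak-to-peak.

The compression artifact follows the five-harmonic quasiperiodic model used
by the suppression filter, with jittered compression intervals and slowly
drifting harmonic amplitudes, so filter behaviour can be scored against an
exactly known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_core import DEFAULT_FS, CCMarks, SignalRecord, SignalTrace
from .cpr_filter import instantaneous_frequency

#: typical decaying harmonic amplitude profile of the artifact (mV)
DEFAULT_HARMONICS = (0.5, 0.3, 0.2, 0.1, 0.05)


@dataclass
class RhythmSpec:
    """Specification of one clean rhythm trace."""

    kind: str  # VF / ORG / ASY
    amplitude: float  # target peak-to-peak amplitude, mV
    rate: float = 5.0  # Hz: fibrillation frequency (VF) or heart rate (ORG)
    duration: float = 9.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"VF", "ORG", "ASY"}:
            raise ValueError(f"unknown rhythm kind {self.kind!r}")
        if self.kind == "VF":
            if not (self.amplitude > 0.2):
                raise ValueError("coarse VF requires peak-to-peak amplitude > 0.2 mV")
            if not (2.5 <= self.rate <= 7.5):
                raise ValueError("VF fibrillation frequency must lie in [2.5, 7.5] Hz")
        elif self.kind == "ASY":
            if not (0 < self.amplitude < 0.1):
                raise ValueError("asystole requires peak-to-peak amplitude < 0.1 mV")
        elif self.kind == "ORG":
            if not (0.5 <= self.rate <= 3.5):
                raise ValueError("organized rhythm rate must lie in [0.5, 3.5] Hz")
            if not (self.amplitude > 0):
                raise ValueError("amplitude must be positive")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")


@dataclass
class ArtifactSpec:
    """Specification of one compression-artifact realization."""

    rate: float = 110.0  # compressions per minute
    rate_jitter: float = 0.05  # fractional SD of the inter-compression interval
    harmonic_amplitudes: Sequence[float] = DEFAULT_HARMONICS
    amplitude_drift: float = 0.05  # fractional drift SD per second
    duration: float = 9.0  # s
    seed: int = 0
    phase_random: bool = True

    def __post_init__(self) -> None:
        if not (80.0 <= self.rate <= 160.0):
            raise ValueError("compression rate must lie in [80, 160] cpm")
        amps = np.asarray(self.harmonic_amplitudes, dtype=float)
        if amps.size != 5 or np.any(amps < 0):
            raise ValueError("need 5 non-negative harmonic amplitudes")
        if self.rate_jitter < 0 or self.amplitude_drift < 0:
            raise ValueError("jitter and drift must be non-negative")


@dataclass
class ArtifactRealization:
    """Artifact trace plus the exact generative state for oracle checks."""

    trace: SignalTrace
    marks: CCMarks
    coeff_paths: np.ndarray  # (n, 5) instantaneous cosine amplitudes c_k(n)
    phase_paths: np.ndarray  # (n, 5) instantaneous phases of each harmonic

    def forward_model(self) -> np.ndarray:
        """Re-synthesize the trace from the stored coefficient/phase paths."""
        return np.sum(self.coeff_paths * np.cos(self.phase_paths), axis=1)


# ---------------------------------------------------------------------------
# Clean rhythms
# ---------------------------------------------------------------------------


def _scale_pkpk(x: np.ndarray, target: float) -> np.ndarray:
    span = x.max() - x.min()
    if span <= 0:
        return x
    return x * (target / span)


def gen_rhythm(spec: RhythmSpec, fs: float = DEFAULT_FS) -> SignalTrace:
    """Generate one clean rhythm trace at the working sampling rate."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs

    if spec.kind == "VF":
        # narrow-band noise around the fibrillation frequency
        lo = max(0.5, spec.rate - 1.0)
        hi = min(fs / 2 - 1.0, spec.rate + 1.0)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        # pre-roll lets the band-pass reach steady state before t=0
        pre = int(2 * fs)
        raw = sps.sosfilt(sos, rng.standard_normal(n + pre))[pre:]
        am = 1.0 + 0.25 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
        x = _scale_pkpk(raw * am, spec.amplitude)
    elif spec.kind == "ORG":
        x = _qrs_train(spec, rng, fs, n, t)
    else:  # ASY
        sos = sps.butter(2, 1.0, btype="lowpass", fs=fs, output="sos")
        pre = int(2 * fs)
        raw = sps.sosfilt(sos, rng.standard_normal(n + pre))[pre:]
        x = _scale_pkpk(raw, spec.amplitude)
    return SignalTrace(x, fs=fs)


def _qrs_template(fs: float, width_s: float = 0.1) -> np.ndarray:
    """Sharp biphasic deflection: derivative of a Gaussian, ~100 ms wide."""
    half = int(round(width_s * fs / 2))
    tt = np.arange(-half, half + 1) / fs
    sigma = width_s / 5.0
    tpl = -tt * np.exp(-(tt**2) / (2 * sigma**2))
    return tpl / (tpl.max() - tpl.min())


def _qrs_train(spec: RhythmSpec, rng: np.random.Generator, fs, n, t) -> np.ndarray:
    x = np.zeros(n)
    tpl = _qrs_template(fs)
    half = (len(tpl) - 1) // 2
    period = 1.0 / spec.rate
    beat = 0
    while True:
        center = (beat + 0.5) * period
        if center >= spec.duration:
            break
        ci = int(round(center * fs))
        lo, hi = ci - half, ci + half + 1
        s0 = max(0, -lo)
        s1 = len(tpl) - max(0, hi - n)
        x[max(0, lo) : min(n, hi)] += tpl[s0:s1] * spec.amplitude
        # low, smooth T-wave hump after the QRS complex
        t_center = center + 0.25 * min(period, 0.8)
        tw = 0.12 * spec.amplitude * np.exp(-((t - t_center) ** 2) / (2 * 0.05**2))
        x += tw
        beat += 1
    x += 0.01 * spec.amplitude * rng.standard_normal(n)
    return x


# ---------------------------------------------------------------------------
# Compression artifact
# ---------------------------------------------------------------------------


def gen_marks(spec: ArtifactSpec) -> CCMarks:
    """Jittered compression instants covering [0, duration)."""
    rng = np.random.default_rng(spec.seed)
    period = 60.0 / spec.rate
    times = [0.0]
    while times[-1] < spec.duration:
        dt = period * (1.0 + spec.rate_jitter * rng.standard_normal())
        dt = float(np.clip(dt, 0.25, 1.5))
        times.append(times[-1] + dt)
    marks = np.asarray(times)
    return CCMarks(marks[marks < spec.duration])


def gen_artifact(spec: ArtifactSpec, fs: float = DEFAULT_FS) -> ArtifactRealization:
    """Synthesize the quasiperiodic artifact exactly from its harmonic model.

    Harmonic amplitudes drift as slow geometric random walks; phases are the
    accumulated compression phase (so the trace is exactly reproducible from
    the stored coefficient and phase paths).  Outside compression intervals
    the artifact is zero.
    """
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from mark jitter
    marks = gen_marks(spec)
    n = int(round(spec.duration * fs))
    f_o = instantaneous_frequency(marks, n, fs)
    active = f_o > 0
    theta = np.cumsum(np.where(active, 2 * np.pi * f_o / fs, 0.0))
    k = np.arange(1, 6)
    phase0 = rng.uniform(0, 2 * np.pi, size=5) if spec.phase_random else np.zeros(5)
    phases = np.outer(theta, k) + phase0

    amps = np.asarray(spec.harmonic_amplitudes, dtype=float)
    if spec.amplitude_drift > 0:
        steps = rng.standard_normal((n, 5)) * (spec.amplitude_drift / np.sqrt(fs))
        drift = np.exp(np.cumsum(steps, axis=0))
    else:
        drift = np.ones((n, 5))
    coeffs = amps[None, :] * drift
    coeffs[~active] = 0.0

    x = np.sum(coeffs * np.cos(phases), axis=1)
    return ArtifactRealization(
        trace=SignalTrace(x, fs=fs), marks=marks, coeff_paths=coeffs, phase_paths=phases
    )


def gen_depth_channel(
    marks: CCMarks, n: int, fs: float, depth_mm: float = 36.0, seed: int = 0
) -> SignalTrace:
    """Smoothed compression-depth pulse train with peaks near ``depth_mm``."""
    rng = np.random.default_rng(seed)
    pulses = np.zeros(n)
    idx = np.round(marks.t_k * fs).astype(int)
    idx = idx[idx < n]
    pulses[idx] = depth_mm * (1.0 + 0.1 * rng.standard_normal(idx.size))
    width = int(round(0.25 * fs))
    kernel = np.hanning(width)
    cd = np.convolve(pulses, kernel, mode="same")
    return SignalTrace(np.clip(cd, 0, None), fs=fs)


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------

def _inband_power(x: np.ndarray, fs: float) -> float:
    """Mean power inside the 0.5-30 Hz analysis band."""
    f, psd = sps.welch(x, fs=fs, nperseg=min(len(x), 1024))
    sel = (f >= 0.5) & (f <= 30.0)
    return float(np.trapezoid(psd[sel], f[sel]))


def _allocate(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n records to classes."""
    keys = sorted(mix)
    raw = {k: n * mix[k] for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    rem = n - sum(counts.values())
    order = sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    return counts


def gen_record(
    kind: str,
    snr_db: float,
    duration: float = 27.0,
    seed: int = 0,
    record_id: str = "",
    patient_id: str = "",
    fs: float = DEFAULT_FS,
) -> SignalRecord:
    """One corrupted record: clean rhythm + artifact scaled to in-band SNR."""
    rng = np.random.default_rng(seed)
    if kind == "VF":
        spec = RhythmSpec(
            kind="VF",
            amplitude=rng.uniform(0.4, 1.5),
            rate=rng.uniform(3.0, 6.5),
            duration=duration,
            seed=int(rng.integers(2**31)),
        )
    elif kind == "ORG":
        spec = RhythmSpec(
            kind="ORG",
            amplitude=rng.uniform(0.6, 1.5),
            rate=rng.uniform(0.7, 2.5),
            duration=duration,
            seed=int(rng.integers(2**31)),
        )
    elif kind == "ASY":
        spec = RhythmSpec(
            kind="ASY",
            amplitude=rng.uniform(0.02, 0.08),
            duration=duration,
            seed=int(rng.integers(2**31)),
        )
    else:
        raise ValueError(f"unknown rhythm kind {kind!r}")
    clean = gen_rhythm(spec, fs=fs)

    art_spec = ArtifactSpec(
        rate=rng.uniform(88.0, 156.0),
        rate_jitter=0.03,
        duration=duration,
        seed=int(rng.integers(2**31)),
    )
    art = gen_artifact(art_spec, fs=fs)

    p_clean = _inband_power(clean.samples, fs)
    p_art = _inband_power(art.trace.samples, fs)
    scale = np.sqrt(p_clean / p_art / 10.0 ** (snr_db / 10.0)) if p_art > 0 else 0.0
    artifact = SignalTrace(art.trace.samples * scale, fs=fs)

    depth = float(np.clip(rng.normal(36.0, 6.0), 21.0, 53.0))
    cd = gen_depth_channel(art.marks, clean.n, fs, depth_mm=depth, seed=int(rng.integers(2**31)))

    return SignalRecord(
        ecg=SignalTrace(clean.samples + artifact.samples, fs=fs),
        cd=cd,
        cc_marks=art.marks,
        rhythm_label=kind,
        record_id=record_id,
        patient_id=patient_id,
        clean=clean,
        artifact=artifact,
    )


def gen_corpus(
    n_records: int,
    class_mix: dict[str, float] | None = None,
    snr_db: float = 0.0,
    seed: int = 0,
    duration: float = 27.0,
) -> list[SignalRecord]:
    """Deterministic corpus of corrupted records with ground truth retained.

    ``class_mix`` maps rhythm kind to proportion (must sum to 1); allocation
    is by largest remainder so the per-class counts are exact.  Each record
    gets its own child seed so the corpus is reproducible byte-for-byte.
    """
    mix = class_mix or {"VF": 1 / 3, "ORG": 1 / 3, "ASY": 1 / 3}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    counts = _allocate(n_records, mix)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_records)
    records = []
    i = 0
    for kind in sorted(counts):
        for j in range(counts[kind]):
            rec = gen_record(
                kind,
                snr_db=snr_db,
                duration=duration,
                seed=int(child_seeds[i] % (2**31)),
                record_id=f"rec{i:04d}",
                patient_id=f"pat{i:04d}",
            )
            records.append(rec)
            i += 1
    return records
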