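"""Per-window discrimination features computed on the filtered ECG.

Six features per 3-s window:

* ``p_lea`` — energy of the 2.5-Hz-high-passed window (low-electrical-activity
  rhythms have almost none);
* ``l_min`` — minimum curve length over the six non-overlapping 0.5-s
  subintervals, a floor-bounded measure of the quietest half second;
* ``bS`` — slope baseline: 10th percentile of the max-normalized smoothed
  squared slope (organized rhythms hug the baseline between QRS complexes);
* ``nP`` — number of slope peaks above a fixed threshold (fibrillation shows
  many, organized rhythms one per beat);
* ``p_fib`` — power fraction in the 2.5-7.5 Hz fibrillation band;
* ``p_h`` — power fraction above 12 Hz, where QRS harmonics live.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .signal_core import DEFAULT_FS, WINDOW_S
from .cpr_filter import FilterConfig, lms_suppress
from .signal_core import SignalRecord, bandpass_ecg, segment_windows

WINDOW_SAMPLES = int(round(WINDOW_S * DEFAULT_FS))  # 750
SUBINTERVAL_SAMPLES = int(round(0.5 * DEFAULT_FS))  # 125


@dataclass
class FeatureConfig:
    lea_highpass_cutoff: float = 2.5  # Hz
    slope_window_ms: float = 100.0  # moving-average span for the squared slope
    peak_threshold: float = 0.2  # on the max-normalized slope, in (0, 1)
    fib_band: tuple[float, float] = (2.5, 7.5)  # Hz
    high_band_low_edge: float = 12.0  # Hz
    high_band_high_edge: float = 30.0  # analysis bandwidth upper edge
    fft_len: int = 1024

    def __post_init__(self) -> None:
        nyq = DEFAULT_FS / 2
        if not (0 < self.fib_band[0] < self.fib_band[1] < nyq):
            raise ValueError("fibrillation band must lie inside (0, fs/2)")
        if not (0 < self.high_band_low_edge < self.high_band_high_edge <= nyq):
            raise ValueError("high band must lie inside (0, fs/2]")
        if self.fft_len < WINDOW_SAMPLES:
            raise ValueError("fft_len must be at least the window length")
        if not (0 < self.peak_threshold < 1):
            raise ValueError("peak_threshold must lie in (0, 1)")


@dataclass
class WindowFeatures:
    p_lea: float  # mV^2 * samples
    l_min: float  # curve length (>= 0.5 by construction)
    bS: float  # in [0, 1]
    nP: int
    p_fib: float  # in [0, 1]
    p_h: float  # in [0, 1]
    degenerate: bool = False  # identically-zero window

    def svm_vector(self) -> np.ndarray:
        return np.array([self.bS, float(self.nP), self.p_fib, self.p_h])


def _check_window(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (WINDOW_SAMPLES,):
        raise ValueError(f"expected a {WINDOW_SAMPLES}-sample window, got shape {x.shape}")
    return x


@lru_cache(maxsize=4)
def _lea_sos(cutoff: float) -> np.ndarray:
    return sps.butter(5, cutoff, btype="highpass", fs=DEFAULT_FS, output="sos")


def highpass_lea(window: np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Order-5 Butterworth high-pass (2.5 Hz) that strips slow fluctuations."""
    cfg = config or FeatureConfig()
    x = _check_window(window)
    return sps.sosfilt(_lea_sos(cfg.lea_highpass_cutoff), x)


def compute_p_lea(s_lea: np.ndarray) -> float:
    """Energy of the high-passed window: sum of squared samples."""
    x = _check_window(s_lea)
    return float(np.sum(x * x))


def compute_l_min(s_lea: np.ndarray, fs: float = DEFAULT_FS) -> float:
    """Minimum curve length over the six non-overlapping 0.5-s subintervals.

    Each subinterval contributes L_k = sum sqrt(ds^2 + Ts^2) over its samples,
    with ds the first difference (defined as 0 at the window start), so a
    constant subinterval attains the floor 125 * Ts = 0.5 exactly.
    """
    x = _check_window(s_lea)
    ts = 1.0 / fs
    ds = np.empty_like(x)
    ds[0] = 0.0
    ds[1:] = np.diff(x)
    terms = np.sqrt(ds * ds + ts * ts)
    lk = terms.reshape(-1, SUBINTERVAL_SAMPLES).sum(axis=1)
    return float(lk.min())


def slope_magnitude(window: np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Max-normalized moving average of the squared first difference.

    The moving average uses reflected padding at the window start so the
    output has full length without a biased-low initial transient.  Returns
    the all-zero array for an identically constant window.
    """
    cfg = config or FeatureConfig()
    x = _check_window(window)
    n_avg = int(round(cfg.slope_window_ms / 1000.0 * DEFAULT_FS))
    sq = np.empty_like(x)
    sq[1:] = np.diff(x) ** 2
    sq[0] = sq[1]  # reflection: ds(0) mirrors ds(1)
    pad = sq[1 : n_avg][::-1]
    d = np.convolve(np.concatenate([pad, sq]), np.ones(n_avg) / n_avg, mode="valid")
    m = d.max()
    if m <= 0:
        return np.zeros_like(d)
    return d / m


def slope_features(
    window: np.ndarray, config: FeatureConfig | None = None
) -> tuple[float, int]:
    """Slope baseline bS (10th percentile) and peak count nP.

    Peaks are local maxima of the normalized slope above the fixed threshold,
    separated by at least one slope-window (100 ms) so ripple on a single
    deflection is not double-counted.  The window maximum itself always
    counts, hence nP >= 1 for any non-constant window.  A degenerate
    (constant) window yields (0.0, 0).
    """
    cfg = config or FeatureConfig()
    dbar = slope_magnitude(window, cfg)
    if not dbar.any():
        return 0.0, 0
    bs = float(np.percentile(dbar, 10.0))
    n_sep = int(round(cfg.slope_window_ms / 1000.0 * DEFAULT_FS))
    # sentinels let maxima at the window edges register as peaks
    padded = np.concatenate([[-1.0], dbar, [-1.0]])
    cands, _ = sps.find_peaks(padded, height=cfg.peak_threshold)
    # enforce the separation left to right: deterministic and insensitive to
    # sub-ulp reorderings of near-equal peak heights
    count = 0
    last = -n_sep
    for p in cands:
        if p - last >= n_sep:
            count += 1
            last = p
    return bs, count


def spectral_features(
    window: np.ndarray, config: FeatureConfig | None = None
) -> tuple[float, float]:
    """Power fractions in the fibrillation band and the high band.

    Hamming window, zero-padded 1024-point FFT, PSD normalized to unit total
    power over the positive frequencies.  A zero window returns (0, 0).
    """
    cfg = config or FeatureConfig()
    x = _check_window(window)
    w = np.hamming(WINDOW_SAMPLES)
    spec = np.fft.rfft(x * w, n=cfg.fft_len)
    psd = np.abs(spec) ** 2
    total = psd.sum()
    if total <= 0:
        return 0.0, 0.0
    psd /= total
    f = np.fft.rfftfreq(cfg.fft_len, d=1.0 / DEFAULT_FS)
    fib = (f >= cfg.fib_band[0]) & (f <= cfg.fib_band[1])
    high = (f >= cfg.high_band_low_edge) & (f <= cfg.high_band_high_edge)
    return float(psd[fib].sum()), float(psd[high].sum())


def window_features(window: np.ndarray, config: FeatureConfig | None = None) -> WindowFeatures:
    """All six features for one filtered 3-s window."""
    cfg = config or FeatureConfig()
    x = _check_window(window)
    s_lea = highpass_lea(x, cfg)
    p_lea = compute_p_lea(s_lea)
    l_min = compute_l_min(s_lea)
    bs, np_count = slope_features(x, cfg)
    p_fib, p_h = spectral_features(x, cfg)
    degenerate = not np.any(x)
    return WindowFeatures(
        p_lea=p_lea, l_min=l_min, bS=bs, nP=np_count, p_fib=p_fib, p_h=p_h,
        degenerate=degenerate,
    )


FEATURE_NAMES = ("p_lea", "l_min", "bS", "nP", "p_fib", "p_h")
SVM_FEATURE_NAMES = ("bS", "nP", "p_fib", "p_h")


def record_window_features(
    record: SignalRecord,
    filter_config: FilterConfig | None = None,
    feature_config: FeatureConfig | None = None,
    preprocessed: bool = False,
):
    """Filter a record and compute features for every complete 3-s window.

    Returns a pandas DataFrame with one row per window (columns: the six
    features plus window/segment bookkeeping and record metadata).  Set
    ``preprocessed`` if the ECG is already band-passed at 250 Hz.
    """
    import pandas as pd

    ecg = record.ecg if preprocessed else bandpass_ecg(record.ecg)
    res = lms_suppress(ecg, record.cc_marks, filter_config)
    stacked = segment_windows(res.s_filt.samples, ecg.fs)
    rows = []
    for si in range(stacked.shape[0]):
        for wi in range(stacked.shape[1]):
            feats = window_features(stacked[si, wi], feature_config)
            rows.append(
                {
                    "record_id": record.record_id,
                    "patient_id": record.patient_id,
                    "rhythm_label": record.rhythm_label,
                    "shockable": record.is_shockable,
                    "segment": si,
                    "window": wi,
                    "p_lea": feats.p_lea,
                    "l_min": feats.l_min,
                    "bS": feats.bS,
                    "nP": feats.nP,
                    "p_fib": feats.p_fib,
                    "p_h": feats.p_h,
                }
            )
    return pd.DataFrame(rows)
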