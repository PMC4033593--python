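"""Adaptive suppression of the chest-compression artifact.

The compression artifact is modeled as a quasiperiodic interference whose
fundamental is the instantaneous compression frequency f_o(n), derived from
the compression marks t_k.  An LMS filter tracks the in-phase/quadrature
coefficients of the first five harmonics,

    s_cpr(n) = sum_k  a_k(n) cos(theta_k(n)) + b_k(n) sin(theta_k(n)),

where theta_k is the running phase of harmonic k, accumulated sample by
sample so that rate changes never produce phase jumps.  The filtered ECG is
the plain subtraction s_filt = ecg - s_cpr, so the decomposition is additive
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import CCMarks, SignalTrace

#: default LMS adaptation constant, chosen by the calibration sweep described
#: in docs/methods.md (balance between artifact tracking speed and distortion
#: of the underlying rhythm at the notch frequencies)
DEFAULT_STEP_SIZE = 0.003


class FilterDivergenceError(RuntimeError):
    """LMS coefficients became non-finite during adaptation."""


@dataclass
class FilterConfig:
    n_harmonics: int = 5
    step_size: float = DEFAULT_STEP_SIZE
    passthrough_outside_cc: bool = True
    leakage: float = 0.0  # optional coefficient leakage per step, 0 disables

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not (self.step_size > 0):
            raise ValueError("step_size must be positive")
        if not (0.0 <= self.leakage < 1.0):
            raise ValueError("leakage must lie in [0, 1)")


@dataclass
class FilterResult:
    """Artifact estimate, filtered ECG and the per-sample compression frequency."""

    s_cpr: SignalTrace
    s_filt: SignalTrace
    f_o: np.ndarray


def instantaneous_frequency(marks: CCMarks, n_samples: int, fs: float) -> np.ndarray:
    """Piecewise-constant compression frequency per sample.

    f_o(n) = 1/(t_k - t_{k-1}) on t_{k-1} <= n*Ts < t_k.  Samples before the
    first mark are compression-free (0); after the last mark the final rate is
    held for one compression period, then the signal is treated as
    compression-free again.  Fewer than two marks yields all zeros.
    """
    f_o = np.zeros(n_samples)
    if marks.n < 2:
        return f_o
    t = np.arange(n_samples) / fs
    tk = marks.t_k
    periods = np.diff(tk)
    for k in range(1, marks.n):
        sel = (t >= tk[k - 1]) & (t < tk[k])
        f_o[sel] = 1.0 / periods[k - 1]
    # hold the last rate for one extra period after the final compression
    tail = (t >= tk[-1]) & (t < tk[-1] + periods[-1])
    f_o[tail] = 1.0 / periods[-1]
    return f_o


def lms_suppress(
    ecg: SignalTrace, marks: CCMarks, config: FilterConfig | None = None
) -> FilterResult:
    """Estimate and subtract the compression artifact from a band-passed ECG.

    Outside compression episodes the artifact estimate is zero (pass-through)
    and the coefficients are frozen; they are re-initialized to zero at the
    start of every compression episode.

    Raises
    ------
    FilterDivergenceError
        if the adaptation diverges (non-finite coefficients); the message
        names the offending step size.
    """
    cfg = config or FilterConfig()
    x = ecg.samples
    n = x.size
    fs = ecg.fs
    f_o = instantaneous_frequency(marks, n, fs)
    active = f_o > 0
    s_cpr = np.zeros(n)

    if active.any():
        nh = cfg.n_harmonics
        k = np.arange(1, nh + 1)
        # running fundamental phase; frozen (no advance) while inactive
        theta = np.cumsum(np.where(active, 2.0 * np.pi * f_o / fs, 0.0))
        # phase matrix for all harmonics, shape (n, nh)
        ph = np.outer(theta, k)
        c = np.cos(ph)
        s = np.sin(ph)
        mu2 = 2.0 * cfg.step_size
        decay = 1.0 - cfg.leakage
        a = np.zeros(nh)
        b = np.zeros(nh)
        prev_active = False
        # overflow en route to the explicit divergence check is expected
        with np.errstate(over="ignore", invalid="ignore"):
            for i in range(n):
                if not active[i]:
                    prev_active = False
                    continue
                if not prev_active:
                    a[:] = 0.0
                    b[:] = 0.0
                prev_active = True
                ci = c[i]
                si = s[i]
                y = a @ ci + b @ si
                e = x[i] - y
                if not np.isfinite(e):
                    raise FilterDivergenceError(
                        f"LMS adaptation diverged with step_size={cfg.step_size}; "
                        "reduce the step size"
                    )
                s_cpr[i] = y
                if decay != 1.0:
                    a *= decay
                    b *= decay
                a += mu2 * e * ci
                b += mu2 * e * si

    s_filt = x - s_cpr
    return FilterResult(
        s_cpr=SignalTrace(s_cpr, fs=fs, start_time=ecg.start_time),
        s_filt=SignalTrace(s_filt, fs=fs, start_time=ecg.start_time),
        f_o=f_o,
    )


def harmonic_basis(marks: CCMarks, n_samples: int, fs: float, n_harmonics: int = 5) -> np.ndarray:
    """Cos/sin regressor matrix (n_samples, 2*n_harmonics) on the accumulated phase.

    The least-squares projection of a signal onto this basis is the
    closed-form stationary solution the LMS filter converges to; it is used
    as an independent oracle in tests and analyses.
    """
    f_o = instantaneous_frequency(marks, n_samples, fs)
    active = f_o > 0
    theta = np.cumsum(np.where(active, 2.0 * np.pi * f_o / fs, 0.0))
    k = np.arange(1, n_harmonics + 1)
    ph = np.outer(theta, k)
    basis = np.hstack([np.cos(ph), np.sin(ph)])
    basis[~active] = 0.0
    return basis
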