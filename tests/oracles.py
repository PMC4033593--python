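"""Independent brute-force reference implementations used by the tests.

Everything here recomputes quantities directly from their definitions with
plain loops (or explicit DFT matrices), deliberately avoiding the package's
own code paths and, where practical, the scipy/numpy conveniences the
implementation relies on.
"""

from __future__ import annotations

import math

import numpy as np

FS = 250.0
TS = 1.0 / FS
WIN = 750
SUB = 125
N_AVG = 25  # 100 ms


def p_lea_loop(s):
    total = 0.0
    for v in s:
        total += v * v
    return total


def l_min_loop(s):
    best = math.inf
    for k in range(6):
        acc = 0.0
        for n in range(k * SUB, (k + 1) * SUB):
            ds = 0.0 if n == 0 else s[n] - s[n - 1]
            acc += math.sqrt(ds * ds + TS * TS)
        best = min(best, acc)
    return best


def slope_curve_loop(s):
    """Max-normalized moving-average squared slope with reflected start."""
    sq = [0.0] * WIN
    for n in range(1, WIN):
        d = s[n] - s[n - 1]
        sq[n] = d * d
    sq[0] = sq[1]
    padded = list(reversed(sq[1:N_AVG])) + sq  # reflection pad, length 774
    d = [sum(padded[n : n + N_AVG]) / N_AVG for n in range(WIN)]
    m = max(d)
    if m <= 0:
        return [0.0] * WIN
    return [v / m for v in d]


def percentile10_loop(values):
    """10th percentile with linear interpolation between order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * 0.10
    lo = int(math.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def peak_count_loop(dbar, threshold=0.2, min_sep=N_AVG):
    """Strict local maxima above threshold with a minimum separation.

    Mirrors the sentinel convention (maxima at the window edges count) and
    the left-to-right enforcement of the separation rule.
    """
    x = [-1.0] + list(dbar) + [-1.0]
    cands = []
    i = 1
    while i < len(x) - 1:
        if x[i - 1] < x[i]:
            # plateau-aware local maximum
            j = i
            while j < len(x) - 1 and x[j + 1] == x[i]:
                j += 1
            if j < len(x) - 1 and x[j + 1] < x[i]:
                mid = (i + j) // 2
                if x[i] >= threshold:
                    cands.append(mid)
                i = j + 1
                continue
        i += 1
    count = 0
    last = -min_sep
    for pos in cands:
        if pos - last >= min_sep:
            count += 1
            last = pos
    return count


_DFT_CACHE = {}


def psd_fractions_matrix(s, fft_len=1024, fib=(2.5, 7.5), high=(12.0, 30.0)):
    """Spectral power fractions via an explicit DFT matrix (no FFT call)."""
    key = fft_len
    if key not in _DFT_CACHE:
        n = np.arange(fft_len)
        k = np.arange(fft_len // 2 + 1)
        _DFT_CACHE[key] = np.exp(-2j * np.pi * np.outer(k, n) / fft_len)
    M = _DFT_CACHE[key]
    w = np.array([0.54 - 0.46 * math.cos(2 * math.pi * i / (WIN - 1)) for i in range(WIN)])
    padded = np.zeros(fft_len)
    padded[:WIN] = np.asarray(s) * w
    spec = M @ padded
    psd = np.abs(spec) ** 2
    total = psd.sum()
    if total <= 0:
        return 0.0, 0.0
    psd /= total
    f = np.arange(fft_len // 2 + 1) * FS / fft_len
    p_fib = psd[(f >= fib[0]) & (f <= fib[1])].sum()
    p_h = psd[(f >= high[0]) & (f <= high[1])].sum()
    return float(p_fib), float(p_h)


def svm_discriminant_loop(support_vectors, dual_weights, bias, gamma, x):
    total = bias
    for sv, w in zip(support_vectors, dual_weights):
        d2 = 0.0
        for a, b in zip(sv, x):
            d2 += (a - b) ** 2
        total += w * math.exp(-gamma * d2)
    return total


def auc_pairs_loop(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def lea_scan_loop(p_lea, l_min, shockable, max_loss):
    """Exhaustive threshold scan over the unique-values-plus-midpoints grid."""
    def cands(vals):
        u = sorted(set(vals))
        out = {0.0} | set(u)
        out |= {(a + b) / 2 for a, b in zip(u, u[1:])}
        return sorted(out)

    n_sh = sum(shockable)
    best = None  # (detected, -lost, -a, -b) maximized
    for a in cands(p_lea):
        for b in cands(l_min):
            det = lost = 0
            for p, l, sh in zip(p_lea, l_min, shockable):
                hit = p < a or l < b
                if sh and hit:
                    lost += 1
                elif not sh and hit:
                    det += 1
            if lost <= max_loss * n_sh + 1e-9:
                key = (det, -lost, -a, -b)
                if best is None or key > best[0]:
                    best = (key, a, b)
    if best is None:
        return None
    return best[1], best[2], best[0][0], -best[0][1]
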