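# Methods

This note documents the models, the numerical choices, and the reasoning
behind the parameters that matter. It is written for someone who wants to
understand or modify the algorithm, not just run it.

## Signal model and preprocessing

All processing happens at a working rate of 250 Hz, typical of automated
external defibrillators. Input at other rates is converted by rational
polyphase resampling (`scipy.signal.resample_poly`), which is exact for the
common 500 → 250 Hz case. The ECG is band-limited to 0.5–30 Hz with an
order-10 Butterworth band-pass applied **causally** in second-order sections.
A causal filter is the realistic choice for a streaming device; the price is
a settling transient — after a unit step the output falls below 1% only
after ≈ 4.3 s — and a small group delay that affects all rhythm classes
equally. Zero-phase filtering was rejected because a real device cannot be
acausal.

Amplitudes are millivolts throughout. This matters because the LEA detector
thresholds are unitful: with ECG in mV, asystole (peak-to-peak < 0.1 mV)
lands far below the default `P_LEA < 0.44` threshold while coarse VF lands
far above it. The unit convention is fixed but the thresholds are plain
config values, so a different calibration can be substituted.

Diagnosis operates on non-overlapping 9-s segments of three 3-s windows
(750 samples each), aligned to sample 0 of the record; a trailing remainder
shorter than 9 s is dropped.

## Compression-artifact filter

The artifact is modeled as a five-harmonic quasiperiodic interference riding
on the instantaneous compression frequency `f_o(n)`, piecewise constant
between consecutive compression marks (`f_o = 1/(t_k − t_{k−1})` on
`[t_{k−1}, t_k)`). Design choices:

* **Phase accumulation.** The harmonic arguments are running phases
  `φ_k(n) = φ_k(n−1) + 2πk f_o(n) T_s`, not the literal product
  `k·2π·f_o(n)·n`. The product form jumps discontinuously whenever the
  compression rate changes; the accumulated form is continuous and the LMS
  coefficients absorb the (slowly varying) phase offsets.
* **In-phase/quadrature parameterization.** Each harmonic contributes
  `a_k cos φ_k + b_k sin φ_k`, algebraically equivalent to the
  amplitude/phase form `c_k cos(φ_k + ϕ_k)` but linear in the parameters, so
  the LMS update is the standard `w ← w + 2μ e x` with bounded regressors.
* **Step size μ = 0.003** (dimensionless; amplitudes in mV). Chosen by a
  sweep on synthetic mixtures measuring two competing errors: residual
  artifact after convergence on drifting-amplitude artifacts (favors large
  μ) and distortion of an underlying fibrillation waveform through the
  adaptive notches at the harmonic frequencies (favors small μ). At
  μ = 0.003 the residual on a 10%/s-drift artifact is ≈ 10% RMS and the SNR
  gain on VF corrupted at −5 dB is 10.8–14.7 dB across 20 seeds; an order of
  magnitude larger μ halves the SNR gain, an order of magnitude smaller
  fails to track amplitude drift. The value is exposed in `FilterConfig`
  together with an optional leakage factor (default 0).
* **Episode handling.** Samples before the first mark are compression-free;
  after the last mark the final rate is held for one compression period and
  the signal is then treated as compression-free again. The artifact
  estimate is zero outside compression episodes (pass-through) and the
  coefficients restart from zero at each episode onset. Divergence
  (non-finite error) raises an error naming the step size.

For a stationary artifact the LMS steady state coincides with the
least-squares projection onto the 10-dimensional cos/sin basis;
`harmonic_basis` exposes that basis so tests can compute the closed-form
solution independently.

## Window features

* `P_LEA` and `L_min` are computed on `s_LEA`, the window high-passed at
  2.5 Hz (order-5 Butterworth, causal) to remove slow fluctuations while
  preserving the fibrillation band. The curve length uses the first
  difference with `Δs(0) = 0`, so a constant subinterval attains the floor
  `125·T_s = 0.5` exactly; the printed-sum form leaves the first sample's
  difference undefined and this convention closes that gap.
* The slope curve is the 100-ms moving average of the squared first
  difference, max-normalized per window. The moving average uses reflected
  padding at the window start so the first 100 ms are not biased low.
  `bS` is the 10th percentile (linear interpolation between order
  statistics). `nP` counts local maxima above a fixed threshold of 0.2 with
  a minimum separation of 100 ms; the separation is enforced left-to-right,
  which is deterministic and — unlike height-priority suppression — immune
  to sub-ulp reordering of near-equal peak heights. Maxima at the window
  edges count (sentinel padding), so any non-constant window has `nP ≥ 1`.
  An identically constant window is degenerate: `bS = 0`, `nP = 0`.
* Spectral features use a Hamming window and a zero-padded 1024-point FFT;
  the squared magnitude over all positive-frequency bins is normalized to
  total power one. `P_fib` is the fraction in 2.5–7.5 Hz; `P_h` the fraction
  in 12–30 Hz, the upper edge being the analysis bandwidth (configurable —
  only the lower edge is intrinsic to the feature).

`bS`, `nP`, `P_fib`, `P_h` are scale-invariant; `P_LEA` scales quadratically
and `L_min` is not scale-invariant, which is precisely why the LEA detector
works in fixed physical units.

## Classifier

The LEA gate runs first and is strictly sequential: a window it flags never
reaches the SVM. Features for the SVM are standardized with training-set
statistics using the population (divide-by-n) standard deviation, making the
two-point contract {1, 3} → {−1, +1} exact. Class weights default to inverse
class frequency normalized to mean one; the cross-validation grid is
`C ∈ 2^(−2..6)`, `γ ∈ 2^(−6..2)` (log-spaced, configurable). Folds are
stratified by class and grouped by record when record identifiers are
available, so windows of one record never straddle folds; the fold count
degrades gracefully on very small corpora (down to resubstitution when a
class has a single record). The selected `(C, γ)` minimizes the mean fold
BER, ties broken toward smaller `C` then smaller `γ`, and the model is refit
on all training data. The frozen model stores support vectors, dual weights
`α_i y_i`, bias, `γ` and the standardization constants in a versioned JSON
document; the discriminant is evaluated with exact (`fsum`) summation so
symmetric contributions cancel to a true zero, and `f(x) = 0` is no-shock.

LEA threshold calibration is an exhaustive scan over a finite candidate grid
(the observed feature values, their midpoints, and 0 as the detect-nothing
point — complete for threshold rules). It maximizes detected low-activity
windows subject to losing at most 5% of shockable windows, ties going to
fewer shockable losses and then smaller thresholds. A selected coordinate of
0 disables that branch of the OR rule. If nothing is feasible the
detect-nothing thresholds are returned with a warning flag.

## Synthetic data

The generators emulate the signal properties the features rely on, not
cardiac electrophysiology:

* **VF** — band-pass-filtered Gaussian noise (±1 Hz around the fibrillation
  frequency, drawn from 3–6.5 Hz per record) with slow amplitude modulation,
  scaled to a target peak-to-peak amplitude above the 0.2 mV coarse-VF
  floor (0.4–1.5 mV per record).
* **ORG** — a train of biphasic ~100 ms QRS-like deflections (Gaussian
  derivative) at 0.7–2.5 Hz with a small T-wave hump and 1% baseline noise.
* **ASY** — low-pass noise scaled below the 0.1 mV peak-to-peak cap.
* **Artifact** — exactly the five-harmonic forward model the filter assumes,
  with jittered compression intervals (default rates drawn from 88–156 cpm,
  3% interval jitter in the corpus), random initial phases, and harmonic
  amplitudes (0.5, 0.3, 0.2, 0.1, 0.05) mV drifting as slow geometric random
  walks. The realization retains its coefficient and phase paths so the
  trace can be reproduced exactly by the forward model.
* A compression-depth channel (smoothed pulse train, peaks around 36 mm) is
  synthesized so mark re-detection from depth can be exercised.

Records mix a clean rhythm with the artifact scaled to a target SNR measured
as mean power inside the 0.5–30 Hz analysis band, and keep both components
for oracle scoring. Corpus allocation over classes is deterministic (largest
remainder), and every record derives its own seed from a seed sequence, so a
corpus is reproducible byte for byte.

**What passing tests do and do not show.** Because the artifact matches the
filter's model family exactly and the rhythm classes are spectrally clean,
separability is far better than in real out-of-hospital ECG: hold-out
sensitivity and specificity on the synthetic corpus are near 1.0, where
clinical performance of this architecture is in the low-to-mid 90s. The
synthetic results validate the mechanics (filter convergence, feature
definitions, gating, training machinery), not clinical accuracy. Real data
adds model mismatch (non-harmonic artifact content, electrode motion),
rhythm morphologies outside the three generated classes (fine VF, VT,
agonal rhythms), and annotation noise.

## Evaluation choices

* The end-to-end study in the test suite uses 72 records × 27 s
  (216 segments, balanced VF/ORG/ASY) at 0 dB SNR, trained on every second
  record and evaluated on the rest — large enough for stable rates while
  keeping the suite fast.
* Confidence intervals use a record-level percentile bootstrap (whole
  records resampled with replacement, seeded; one-sided lower bound). This
  addresses the same within-record clustering a longitudinal model-based
  adjustment would, without committing to an estimating-equation
  implementation; reports carry a method tag so the intervals are never
  presented as model-based.
* AUC uses the Mann–Whitney identity with midrank tie handling.
* PPV is reported in percent from sensitivity, specificity and VF
  prevalence; the reference evaluation uses the rounded operating point
  (0.910, 0.966), matching the precision at which such operating points are
  reported. Using unrounded rates would shift the PPV by well under one
  tenth of a percentage point across the prevalence range.

## Known limitations

* The compression artifact generator and the filter share the same harmonic
  model family; the synthetic SNR-gain results are therefore an upper bound
  on what mismatched real artifacts allow.
* Mark extraction is assumed given (or derived from a clean synthetic depth
  channel); noisy depth signals and missed compressions are not modeled.
* Only VF among shockable rhythms is generated (no ventricular tachycardia
  templates); ORG covers organized nonshockable rhythms generically.
* WFDB input is not supported in this build; records are exchanged as CSV
  (`time,ecg_mv[,cd_mm]`) plus a plain-text marks file.
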