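# cprrhythm

ECG rhythm analysis **during ongoing chest compressions**. Interrupting
cardiopulmonary resuscitation (CPR) to let a defibrillator analyze the rhythm
costs perfusion and lowers the chance of defibrillation success, but chest
compressions corrupt the ECG so badly that a standard shock-advice algorithm
(SAA) cannot run over them. `cprrhythm` implements a complete analysis chain
for this problem, aimed at researchers in resuscitation signal processing:

1. **CPR artifact suppression.** The compression artifact is modeled as a
   quasiperiodic interference whose fundamental is the instantaneous
   compression frequency `f_o(n) = 1/(t_k − t_{k−1})`, derived from the
   compression instants `t_k` (obtained from a compression-depth channel).
   An LMS adaptive filter tracks the in-phase/quadrature coefficients of the
   first five harmonics,

       s_cpr(n) = Σ_{k=1..5} c_k(n) cos(k·θ(n) + φ_k(n)),   θ̇ = 2π f_o,

   and the filtered ECG is `s_filt = s − s_cpr`.

2. **Shock-advice algorithm on the filtered ECG.** Two sequential stages per
   3-s window:
   * a **low-electrical-activity (LEA) detector**: the window is no-shock if
     `P_LEA < 0.44` *or* `L_min < 0.63`, where `P_LEA = Σ s_LEA²(n)` is the
     energy of the 2.5-Hz-high-passed window and `L_min` is the minimum curve
     length `Σ √(Δs_LEA² + T_s²)` over the six 0.5-s subintervals;
   * a **class-weighted Gaussian-kernel SVM** on four standardized features —
     slope baseline `bS` (10th percentile of the max-normalized smoothed
     squared slope), slope peak count `nP`, and the spectral power fractions
     `P_fib` (2.5–7.5 Hz) and `P_h` (above 12 Hz) — with
     `f(x) = Σ α_i y_i exp(−γ‖x − x_i‖²) + b`, shock iff `f(x) > 0`.
     `(C, γ)` are chosen by stratified, record-grouped 5-fold cross-validation
     minimizing the balanced error rate `BER = 1 − (TPR + TNR)/2`.

   Three consecutive window decisions are combined by **majority vote** into
   one diagnosis per 9-s segment.

3. **Synthetic physiology.** Seedable generators for coarse ventricular
   fibrillation (VF), organized rhythms (ORG) and asystole (ASY), plus the
   five-harmonic compression artifact with jittered rate and drifting
   amplitudes, so the whole chain is testable without clinical data.

4. **Evaluation.** Sensitivity/specificity, BER, prevalence-dependent
   positive predictive value, ROC AUC, LEA threshold calibration under a
   bounded shockable-loss constraint, and record-level bootstrap confidence
   intervals.

## Worked example

Simulate a labeled corpus (24 records, ~balanced VF/ORG/ASY, artifact mixed
at 0 dB in-band SNR), train the full algorithm, and evaluate it:

```sh
$ cprr simulate --n 24 --mix vf=0.34,org=0.33,asy=0.33 --snr 0 --seed 42 --out corpus
wrote 24 records to corpus

$ cprr train --features train.csv --out model.json --seed 0
model saved to model.json (C=0.25, gamma=0.015625, CV BER=0.000)

$ cprr classify --input corpus/rec0008.csv --marks corpus/rec0008.marks \
       --model model.json --out diag.csv
rec0008 segment 0: NSh
rec0008 segment 1: NSh
rec0008 segment 2: NSh

$ cprr evaluate --corpus corpus --model model.json --report report.json --ci-seed 7
segments: Se=1.000 Sp=1.000 BER=0.000 (report -> report.json)
```

(`train.csv` is the concatenated output of `cprr features` over the corpus
records with their manifest labels; see `cprrhythm.evaluation.build_feature_table`
for the one-call equivalent.) Record `rec0008` is an organized rhythm: every
3-s window and hence every 9-s segment is diagnosed no-shock (`NSh`). The
cross-validated BER of 0.000 and the perfect hold-in Se/Sp reflect how cleanly
the synthetic rhythm classes separate at this corpus size — real out-of-hospital
ECG is far harder (see `docs/methods.md` for what the generator does and does
not emulate).

A per-window feature row looks like:

```
record_id,segment,window,p_lea,l_min,bS,nP,p_fib,p_h
rec0008,0,0,20.52,2.80,0.0015,6,0.341,0.236
```

— high `p_lea`/`l_min` (clear electrical activity, so the LEA gate passes it
to the SVM), low slope baseline and high `P_h` (QRS harmonics), which is the
organized-rhythm signature.

## Layout

| module | contents |
|---|---|
| `cprrhythm.signal_core` | traces, records, CSV I/O, resampling, 0.5–30 Hz band-pass, 9-s/3-s segmentation |
| `cprrhythm.cpr_filter` | instantaneous compression frequency, harmonic LMS artifact suppression |
| `cprrhythm.features` | the six per-window features (`P_LEA`, `L_min`, `bS`, `nP`, `P_fib`, `P_h`) |
| `cprrhythm.classifier` | LEA detector, standardization, SVM training/decision, majority vote, model JSON |
| `cprrhythm.synthetic` | seedable VF/ORG/ASY and artifact generators, corpus builder |
| `cprrhythm.evaluation` | Se/Sp/BER/PPV/AUC, LEA threshold calibration, record-level bootstrap CIs |
| `cprrhythm.cli` | the `cprr` command (`simulate`, `filter`, `features`, `train`, `classify`, `evaluate`) |
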