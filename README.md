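# stnseq

Sequential-decision (expanded judgment) behavior modelling and
subthalamic-cortical β-band analysis, exercised end to end on synthetic data
with known ground truth.

In the expanded judgment task an observer watches a sequence of binary cues
(left/right), each matching the true direction with validity 0.7 and arriving
every 800 ms, and responds whenever they feel they have enough evidence.
Paradigms of this kind are used to study how the subthalamic nucleus (STN)
and frontal cortex track accumulating evidence and react to *local conflict*
— a cue that contradicts the one immediately before it.  `stnseq` packages
the full computational tool chain for such a study, for researchers in
computational/cognitive neuroscience who want to develop, validate or teach
these analyses without access to patient recordings:

- **Evidence-accumulation models of choice.**  Four nested recurrences for
  the decision variable driven by cues S_t ∈ {−1, +1}, with DV₀ = 0:

  - M1: DVₜ = DVₜ₋₁ + Sₜ
  - M2: DVₜ = (1−λ) DVₜ₋₁ + Sₜ
  - M3: DVₜ = DVₜ₋₁ + (1 + ω·SAₜ) Sₜ
  - M4: DVₜ = (1−λ) DVₜ₋₁ + (1 + ω·SAₜ) Sₜ

  where λ is a forgetting rate, ω a bonus for cue repetitions
  (SAₜ = 1 iff Sₜ = Sₜ₋₁), linked to choice through
  ln P(R)/P(L) = β₀ + β₁·DVₜ, fitted by maximum likelihood and compared by
  BIC = k·ln n − 2·ln L̂.  A logistic *commitment regression* asks whether
  stopping is driven by accumulated evidence, by cue repetition, or both.
- **Bayesian normalization and surprise regressors.**  Cortical integrators
  Y_L, Y_R with an STN normalization term STNₜ = ln(exp Y_L,ₜ + exp Y_R,ₜ)
  subtracted after every cue (so that Y_R − Y_L reproduces the fitted DV
  exactly), plus Shannon surprise −ln P(cue_i | cue_1..i−1) as a
  global-conflict regressor.
- **A baseline-free spectral pipeline.**  Continuous multitaper band power
  (400 ms window, 50 ms steps; β 13–30 Hz, θ 2–8 Hz), log transform,
  zero-phase 0.5 Hz high-pass of the power series, then cue epoching
  (−500 to 800 ms) — the order matters because the short SOA never lets
  power return to a baseline.
- **Cluster-based permutation statistics.**  Per-timepoint GLMs on z-scored
  regressors and same/different contrasts, corrected over time (and
  frequency) by the permutation null of the maximum cluster mass, with
  pooled-epoch, Freedman–Lane and group-level sign-flip schemes.
- **Time-resolved connectivity.**  Coherence from epoch-summed
  cross-spectra and the (signed, debiased) weighted phase-lag index on a
  1–30 Hz grid, with cluster-corrected condition contrasts over 0–1600 ms.
- **A ground-truth generator.**  Behavioral agents with explicit stopping
  policies, and a two-channel (STN + cortex) 300 Hz signal generator with
  regressor-modulated β bursts, a dip-then-rise local-conflict profile that
  carries over into the next cue, condition-dependent phase-lagged coupling
  and 1/f background noise — every downstream stage can be validated
  against what was injected.

## Worked example

`examples/` contains one short script per capability.
`examples/03_band_power_conflict.py` simulates a session, runs the power
pipeline and the conflict contrast, and prints:

```
recording: 402 s at 300 Hz, 348 cue onsets
epochs: 348 cues x 27 timepoints (-500 to 800 ms)

different-minus-same contrast (114 vs 54 observations):
  cluster   750- 1400 ms  sign +1  mass   119.1  p_fwe 0.001  d +2.25
  cluster    50-  650 ms  sign -1  mass  -131.3  p_fwe 0.001  d -2.36
  cluster  1500- 1600 ms  sign -1  mass   -18.7  p_fwe 0.018  d -1.17
```

The early negative cluster is the β-power dip right after a conflicting
("different") cue; the positive cluster from 750 ms onward is the β rebound
that outlasts the cue and carries into the next one.  Masses are sums of
pointwise t values, `p_fwe` the family-wise-corrected permutation p-value,
`d` the cluster Cohen's d.  `examples/05_full_pipeline.py` (or
`stnseq run-all --seed 21 --out <dir>`) runs the whole chain — behavior,
model fits, regressors, recording, band power, GLM, contrast, coherence —
into a run directory with a checksum manifest; identical seeds reproduce
every artifact bit for bit.

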