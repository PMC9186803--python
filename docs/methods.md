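# Methods

This note documents the models, estimators and design choices implemented in
`stnseq`, and what the synthetic-data generator does and does not emulate.

## Task model and behavior

The expanded judgment task presents binary cues (left = −1, right = +1) at a
fixed 800 ms stimulus onset asynchrony (200 ms cue + 600 ms interstimulus
interval).  Each cue independently matches the trial's true direction with
validity v = 0.7; directions are equiprobable across trials.  Useful closed
forms: a single-cue strategy scores v = 70%, chance is 50%, and two
consecutive cues agree with probability v² + (1−v)² = 0.58.  The ideal
observer takes a majority vote over the cues actually sampled; when
summarizing behavior an exact tie credits 0.5 in expectation (a seeded coin
flip is available when an actual choice is needed), which keeps summaries
deterministic while matching random tie-breaking on average.  Agents that
never reach a decision within `max_cues` either make a forced choice from
the current decision variable (the generator's default) or leave the trial
unanswered, in which case summaries exclude it and count it.

## Accumulator models and fitting

The four recurrences (perfect integration; forgetting λ ∈ [0, 1]; repetition
bonus ω; both) are defined in the README.  The repetition indicator SA_t is
undefined at t = 1, so the bonus term is not applied to the first cue — the
only consistent reading.  The logistic link uses a single slope β₁ on the
decision variable at the moment of choice; only two link parameters are
identifiable per model, and a per-stimulus likelihood variant (every cue
contributes a Bernoulli term for the eventual choice) is exposed as an
option.  Fitting profiles the link out exactly: for each candidate (λ, ω)
the two link parameters are obtained by Newton–Raphson (the inner problem is
concave), and the outer bounded problem over λ ∈ [0, 1], ω ∈ [−2, 2] is
solved by L-BFGS-B from five deterministic starts at ftol 1e-8, so the
profile optimum coincides with the joint MLE.  Models are ranked by
BIC = k ln n − 2 ln L̂ with k counting β₀, β₁ and whichever of λ, ω are
free.  The commitment regression predicts D_t (1 at the stopping cue, 0
before) from the evidence for the eventually chosen option (DV_t signed
toward the final choice) and SA_t, over all cues t ≥ 2; Wald tests at
α = 0.05 classify the stopper.  Complete separation (e.g. a hard
deterministic threshold) triggers a ridge-penalized (λ_ridge = 1) refit with
Wald p-values from the penalized Hessian, and is flagged.

Two caveats discovered while validating: (i) because the choice is the sign
of the decision variable at stopping, the evidence predictor is mechanically
informative even for stopping rules that ignore the cues — a true behavioral
null requires an agent whose *choice* is also random; (ii) for threshold
stoppers with many trials the repetition factor tends to reach significance
alongside evidence, because threshold crossings often coincide with repeats.

## Normalization and surprise regressors

The integrators are updated as
Y_{c,t} = (1−λ) Y_{c,t−1} + (1 + ω SA_t)·[cue = c] − STN_{t−1} with
Y_{L,0} = Y_{R,0} = ln 0.5 and STN_t = ln(exp Y_L,t + exp Y_R,t) evaluated
with log-sum-exp.  Because the normalization term enters both integrators
identically it cancels in the difference, so Y_R,t − Y_L,t equals the
decision variable of the same (λ, ω) exactly; the test suite enforces this
to 1e-10.  Shannon surprise is computed under the true generative validity
(0.7) rather than a fitted value, since it is defined by the task's Bayes
model: with q_i the posterior probability that the true direction equals cue
i (uniform prior, conditionally independent cues), surprise is
−ln[q_i v + (1−q_i)(1−v)].  On realized sequences the normalization and
surprise regressors are strongly anticorrelated — both are monotone
functions of the running count difference — which is why the GLM can include
either as the "global conflict" axis but not meaningfully both.

## Synthetic neural generator

The generator is a validation instrument, not a biophysical model.  Each cue
contributes a 21.5 Hz burst (Hann envelope, 0.05–0.75 s post-onset) whose
amplitude is a₀ plus weighted z-scored regressors (|evidence|, cue number,
normalization); the local-conflict weight instead multiplies a biphasic
profile (negative Hann lobe 0.10–0.45 s, positive lobe 0.60–1.50 s) so that
"different" cues produce a power dip followed by a rebound that carries into
the next cue.  Negative total amplitudes are clipped at zero and counted.
The cortical channel receives the same β component at a quarter-cycle phase
lag, with coupling gain boosted 0.5–1.25 s after "different" cues, plus its
own independent 1/f noise (spectrally shaped white noise, exponent 1.0,
unit variance); a small constant 5 Hz component keeps the θ band non-empty.
Default effect weights (conflict +0.6, |evidence| +0.3, cue number −0.3,
normalization 0) mirror the qualitative finding pattern the pipeline is
meant to recover — including the *absence* of a normalization effect — at
single-session effect sizes around d ≈ 1.5–2.  What the generator does not
emulate: evoked potentials, burst-duration statistics of real β, spatially
structured noise, artifacts, or any head geometry; passing tests therefore
demonstrate correctness of the estimators and statistics, not that real
recordings would show these effects.

Carrier phase is randomized per trial but constant within it, which makes
within-trial coherence high by construction; coherence conclusions from the
generator concern estimator behavior, not physiological coupling strength.

## Spectral pipeline

Raw signals (300 Hz; a 1 Hz fifth-order zero-phase Butterworth high-pass and
polyphase downsampling are provided for other inputs, and bipolar/ring
montage helpers for multi-contact leads) are decomposed with a sliding
400 ms window in 50 ms steps.  Band power is a single multitaper estimate at
the band center with DPSS half-bandwidth spanning the band — β: 21.5 ±
8.5 Hz, K = ⌊2TW⌋ − 1 = 5 tapers; θ: 5 ± 3 Hz, 1 taper — under the PSD
convention (unit-energy tapers, divided by fs), so that integrating over a
dense grid recovers signal variance (tested to 5% on white noise).  A
per-bin-average mode over the band's FFT bins is available as a switch and
recorded in the output metadata.  The log power series is then high-pass
filtered at 0.5 Hz (fifth-order Butterworth, zero-phase `sosfiltfilt`),
which removes fluctuations slower than the cue rate and any additive
constant (hence amplitude-scale invariance); a 1.25 Hz amplitude modulation
— one cycle per SOA — passes with <0.1% attenuation.  Only then is the power
epoched at −500 to 800 ms around each cue (27 points on the 50 ms grid),
with markers snapped to the nearest grid point (≤25 ms misalignment),
edge-overlapping epochs dropped and counted, and first/last cues flagged.

## Cluster statistics

Per-timepoint OLS on the four z-scored regressors (cue identity coded
different = 1, normalization, |evidence|, cue number; first and last cues
excluded) yields t series per regressor.  Clusters are contiguous runs
(4-connectivity in time × frequency) of |t| above the two-sided parametric
critical value at cluster α = 0.05 (configurable); the cluster statistic is
the mass Σt, and p_fwe = (1 + #{null ≥ observed}) / (1 + n_perm) against the
permutation distribution of the maximum |mass|.  Permutation schemes:
condition-label shuffles for contrasts, joint row shuffles of the design
(equivalently of the data) for the GLM with Freedman–Lane as an option, and
subject-level sign flips for group mode.  Default n_perm = 1000 with the
seed recorded in output.  Cohen's d is the cluster-mean difference over the
pooled SD across epochs (contrast mode), 2·t̄/√df (GLM mode) or the
standardized subject-mean (group mode).  For connectivity contrasts the
difference map is z-scored cell-wise against its own permutation
distribution before cluster forming, since coherence differences have no
parametric t reference.

Exchangeability caveats, found and handled during validation: the carry-over
contrast concatenates each cue's window with the next cue's, so observations
whose following cue ends the trial would border the response period and
post-trial silence — and for evidence-sensitive stoppers that proximity is
condition-dependent ("same" cues precede stopping more often), producing a
spurious late "effect" under a null generator.  Such observations are
excluded by default (`exclude_next_last`).  Even so, pooled single-subject
observations overlap in time and share cues, so epoch-level permutation is
approximate there; the exact test for cohort inference is the group-level
sign-flip on per-subject difference traces, which the pipeline uses whenever
more than one synthetic subject is configured.  Under the null generator the
end-to-end false-positive rate of the default contrast matched its nominal
level in simulation after the exclusion.

## Connectivity

Raw two-channel epochs of −1000 to 1000 ms around each cue (the wider window
buys sliding-window room) are transformed with the same engine on a 1–30 Hz
grid at 1 Hz spacing with ±2.5 Hz smoothing (single taper).  Coherence at
each (t, f) cell is |Σ_e X_e Y_e*| / √(Σ|X|² Σ|Y|²) across epochs; its
small-sample bias E[coh²] ≈ 1/n on independent signals is verified against
the closed form (away from the near-DC cells, where real-valued spectral
coefficients inflate it).  The debiased squared weighted phase-lag index is
computed from the imaginary cross-spectra as
[(ΣIm)² − ΣIm²] / [(Σ|Im|)² − ΣIm²] and reported with the sign of ΣIm, so
the value lies in [−1, 1], flips sign when the lag direction flips (positive
when the first channel leads), is ~0 under instantaneous mixing, and is
insensitive to unequal epoch counts.  Imaginary parts below 1e-12 of the
cross-spectrum magnitude are treated as exact zeros (the estimator is
scale-free and would otherwise amplify rounding noise); all-zero cells are
flagged degenerate.  Directionality measures are deliberately out of scope.
Condition contrasts reuse the carry-over pairing and cluster machinery
above.

## Pipeline and reproducibility

`run_pipeline` executes behavior → model fits → regressors → recording →
band power → GLM → contrast → coherence per synthetic subject from a
YAML/dict config, deriving each stage's seed as SHA-256(global seed : stage
name) mod 2³¹.  Artifacts are plain CSV/JSON except the recording (float32
binary with a JSON sidecar holding fs, channel names and 0-based marker
samples).  The manifest records the config hash, stage seeds, timings and
per-artifact SHA-256 checksums; reruns of the same config and seed are
bit-identical.  The default demo problem sizes (tens of trials per subject,
hundreds to a thousand permutations) keep a full run in the seconds-to-
minutes range while leaving every effect detectable at the generator's
default effect sizes; all sizes are config switches.

## Known limitations

- Single-subject pooled contrasts are approximate under temporal overlap
  (see above); trust group mode for inference.
- The logistic-link fits assume final-choice likelihoods; the per-stimulus
  variant is provided but not the default.
- The generator's β carrier is a fixed-frequency sinusoid; analyses that
  depend on spectral shape within the band (e.g. peak-frequency shifts)
  are outside what it can validate.
- EDF export is not implemented; recordings use the documented raw-binary +
  JSON-sidecar container.
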