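"""Synthetic behavior and neural recordings with known ground truth.

The behavioral generator draws 70%-valid binary cue streams and runs an
evidence-accumulating agent with an explicit stopping policy over them.  The
neural generator renders a two-channel continuous recording ("stn" and
"cortex") at 300 Hz: beta-band (21.5 Hz) bursts time-locked to cue onsets
whose amplitude is modulated by the per-cue regressors, a biphasic
(dip-then-rise) gain profile for the local-conflict (same/different)
effect that carries over into the next cue, condition-dependent phase-lagged
coupling into the cortical channel, and additive 1/f background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .accumulators import AccumulatorParams
from .io import ContinuousRecording
from .task import TaskConfig, TrialRecord

__all__ = [
    "AgentSpec",
    "NeuralSimSpec",
    "simulate_behavior",
    "simulate_choice_model_trials",
    "simulate_recording",
    "powerlaw_noise",
]


@dataclass(frozen=True)
class AgentSpec:
    """Stopping policy of a simulated observer.

    stop_rule "threshold": respond at the first cue where |DV_t| >= threshold
    (threshold >= 1 so the rule can fire).  stop_rule "logistic": after each
    cue stop with probability sigmoid(b0 + b1 |DV_t| + b2 SA_t), coefficients
    in ``stop_beta``.  ``choice_policy`` is "dv_sign" (choose sign of the
    decision variable, ties by coin) or "random" (unbiased coin, a pure
    guesser).
    """

    params: AccumulatorParams = field(default_factory=lambda: AccumulatorParams("M1"))
    stop_rule: str = "threshold"
    threshold: float = 3.0
    stop_beta: tuple[float, float, float] = (-3.0, 1.0, 0.5)
    max_cues: int = 10
    choice_policy: str = "dv_sign"

    def __post_init__(self):
        if self.stop_rule not in ("threshold", "logistic"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")
        if self.stop_rule == "threshold" and self.threshold < 1.0:
            raise ValueError("threshold must be >= 1")
        if self.max_cues < 2:
            raise ValueError("max_cues must be >= 2")
        if self.choice_policy not in ("dv_sign", "random"):
            raise ValueError(f"unknown choice_policy {self.choice_policy!r}")


def _draw_cues(n_trials: int, max_cues: int, validity: float, rng: np.random.Generator):
    true_dir = np.where(rng.random(n_trials) < 0.5, -1, 1).astype(np.int8)
    match = rng.random((n_trials, max_cues)) < validity
    cues = np.where(match, true_dir[:, None], -true_dir[:, None]).astype(np.int8)
    return true_dir, cues


def _dv_traces(cues: np.ndarray, lam: float, omega: float):
    n, m = cues.shape
    dv = np.zeros((n, m))
    sa = np.zeros((n, m), dtype=bool)
    prev = np.zeros(n)
    for t in range(m):
        s = cues[:, t].astype(float)
        if t >= 1:
            sa[:, t] = cues[:, t] == cues[:, t - 1]
        prev = (1.0 - lam) * prev + (1.0 + omega * sa[:, t]) * s
        dv[:, t] = prev
    return dv, sa


def simulate_behavior(
    cfg: TaskConfig,
    agent: AgentSpec,
    n_trials: int,
    rng: np.random.Generator | int,
    *,
    force_response: bool = True,
    rt_mean: float = 0.52,
    rt_sd: float = 0.05,
) -> list[TrialRecord]:
    """Simulate ``n_trials`` of the expanded judgment task.

    The agent accumulates evidence per its accumulator parameters and stops
    when its rule fires; if the rule never fires by ``max_cues`` the agent
    either makes a forced choice from the current decision variable
    (default) or, with ``force_response=False``, leaves the trial
    unanswered (choice None).  Bit-reproducible for a given seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    max_cues = min(agent.max_cues, cfg.max_cues)
    true_dir, cues = _draw_cues(n_trials, max_cues, cfg.validity, rng)
    dv, sa = _dv_traces(cues, agent.params.lam, agent.params.omega)

    if agent.stop_rule == "threshold":
        stop = np.abs(dv) >= agent.threshold
    else:
        b0, b1, b2 = agent.stop_beta
        p_stop = 1.0 / (1.0 + np.exp(-(b0 + b1 * np.abs(dv) + b2 * sa)))
        stop = rng.random((n_trials, max_cues)) < p_stop

    any_stop = stop.any(axis=1)
    first = np.where(any_stop, stop.argmax(axis=1), max_cues - 1)
    n_sampled = first + 1

    dv_at_stop = dv[np.arange(n_trials), first]
    coin = np.where(rng.random(n_trials) < 0.5, -1, 1)
    if agent.choice_policy == "random":
        choice = coin
    else:
        choice = np.where(dv_at_stop > 0, 1, np.where(dv_at_stop < 0, -1, coin))
    rts = np.clip(rng.normal(rt_mean, rt_sd, n_trials), 0.15, None)

    trials = []
    for i in range(n_trials):
        responded = any_stop[i] or force_response
        trials.append(
            TrialRecord(
                trial_id=i,
                true_direction=int(true_dir[i]),
                cues=cues[i, : n_sampled[i]].copy(),
                choice=int(choice[i]) if responded else None,
                rt=float(rts[i]) if responded else None,
            )
        )
    return trials


def simulate_choice_model_trials(
    cfg: TaskConfig,
    params: AccumulatorParams,
    beta0: float,
    beta1: float,
    n_trials: int,
    rng: np.random.Generator | int,
    *,
    min_cues: int = 2,
    max_cues: int = 10,
) -> list[TrialRecord]:
    """Trials whose choices are drawn from the logistic link itself.

    Stopping is uniform over [min_cues, max_cues], independent of the
    decision variable, so the choice likelihood is the only structure a fit
    can exploit — the clean setting for parameter and model recovery.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    true_dir, cues = _draw_cues(n_trials, max_cues, cfg.validity, rng)
    dv, _ = _dv_traces(cues, params.lam, params.omega)
    n_sampled = rng.integers(min_cues, max_cues + 1, n_trials)
    dv_final = dv[np.arange(n_trials), n_sampled - 1]
    p_right = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * dv_final)))
    choice = np.where(rng.random(n_trials) < p_right, 1, -1)
    return [
        TrialRecord(
            trial_id=i,
            true_direction=int(true_dir[i]),
            cues=cues[i, : n_sampled[i]].copy(),
            choice=int(choice[i]),
            rt=0.5,
        )
        for i in range(n_trials)
    ]


@dataclass(frozen=True)
class NeuralSimSpec:
    """Parameters of the continuous two-channel neural generator.

    Effect weights scale the per-cue burst amplitude by the z-scored
    regressors; ``b_same_diff`` drives the biphasic (dip 0.10-0.45 s, rise
    0.60-1.50 s) local-conflict profile, the other weights the standard
    burst envelope (Hann, 0.05-0.75 s).  ``coupling`` "lagged" feeds the
    STN beta component into the cortex channel at ``coupling_lag`` radians
    with gain boosted by ``coupling_boost`` around 0.5-1.25 s after
    "different" cues.  Background noise is 1/f^exponent with unit-variance
    amplitude ``noise_amp`` per channel.
    """

    fs: float = 300.0
    beta_freq: float = 21.5
    theta_freq: float = 5.0
    soa: float = 0.8
    trial_gap: float = 2.0
    burst_amp: float = 1.0
    b_same_diff: float = 0.6
    b_absev: float = 0.3
    b_cuenum: float = -0.3
    b_norm: float = 0.0
    theta_amp: float = 0.15
    coupling: str = "lagged"
    coupling_lag: float = np.pi / 2
    coupling_gain: float = 0.5
    coupling_boost: float = 1.0
    noise_exponent: float = 1.0
    noise_amp: float = 1.0

    def __post_init__(self):
        if self.fs <= 2.0 * self.beta_freq:
            raise ValueError("fs must exceed twice the beta carrier frequency")
        if self.coupling not in ("none", "lagged"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        for w in (self.b_same_diff, self.b_absev, self.b_cuenum, self.b_norm):
            if not np.isfinite(w):
                raise ValueError("effect weights must be finite")


def powerlaw_noise(
    n: int, exponent: float, rng: np.random.Generator, amplitude: float = 1.0
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    if sd > 0:
        shaped /= sd
    return amplitude * shaped


def _hann_window(t: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Hann bump supported on [start, stop] evaluated at times t (seconds)."""
    out = np.zeros_like(t)
    inside = (t >= start) & (t <= stop)
    phase = (t[inside] - start) / (stop - start)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


def _zscore_or_zero(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x)
    if not np.isfinite(s) or s == 0:
        return np.zeros_like(x)
    z = (x - m) / s
    return np.where(np.isfinite(z), z, 0.0)


def simulate_recording(
    trials: Sequence[TrialRecord],
    regressors: pd.DataFrame,
    spec: NeuralSimSpec,
    rng: np.random.Generator | int,
) -> ContinuousRecording:
    """Render a continuous two-channel recording for the given trials.

    ``regressors`` is the per-cue table from
    :func:`stnseq.bayes_norm.regressor_table` (columns trial, cue_index,
    cue_identity_same, abs_evidence, cue_number, bayes_norm).  Cue onsets
    are spaced exactly SOA apart within a trial, trials separated by
    ``trial_gap`` seconds of background, with a 2 s lead-in/lead-out.
    Negative total burst amplitudes are clipped at zero and counted in
    ``meta['n_amp_clipped']``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    fs = spec.fs
    soa_samp = int(round(spec.soa * fs))
    gap_samp = int(round(spec.trial_gap * fs))
    lead = int(round(2.0 * fs))

    reg = regressors.set_index(["trial", "cue_index"])
    # per-cue modulation terms, z-scored across all cues
    z_diff = _zscore_or_zero(1.0 - regressors["cue_identity_same"].to_numpy())
    z_absev = _zscore_or_zero(regressors["abs_evidence"].to_numpy())
    z_cuenum = _zscore_or_zero(regressors["cue_number"].to_numpy())
    z_norm = _zscore_or_zero(regressors["bayes_norm"].to_numpy())
    is_diff = (regressors["cue_identity_same"].to_numpy() == 0.0).astype(float)
    row_of = {key: j for j, key in enumerate(reg.index)}

    # layout: cue onset sample for every (trial, cue)
    onsets, marker_trial, marker_cue = [], [], []
    pos = lead
    for tr in trials:
        for c in range(len(tr.cues)):
            onsets.append(pos + c * soa_samp)
            marker_trial.append(tr.trial_id)
            marker_cue.append(c + 1)
        pos += len(tr.cues) * soa_samp + gap_samp
    n_samples = pos + lead
    onsets = np.asarray(onsets)

    t_rel_max = 1.8  # longest envelope support (carry-over lobe ends at 1.5 s)
    n_env = int(round(t_rel_max * fs))
    t_rel = np.arange(n_env) / fs
    env_burst = _hann_window(t_rel, 0.05, 0.75)
    env_bi = -_hann_window(t_rel, 0.10, 0.45) + _hann_window(t_rel, 0.60, 1.50)
    env_couple = _hann_window(t_rel, 0.50, 1.25)

    amp = np.zeros(n_samples)       # beta amplitude envelope (shared)
    gain = np.zeros(n_samples)      # cortex coupling gain envelope
    n_clipped = 0
    k = 0
    for tr in trials:
        for c in range(len(tr.cues)):
            j = row_of.get((tr.trial_id, c + 1))
            onset = onsets[k]
            k += 1
            if j is None:
                continue
            a_k = (
                spec.burst_amp
                + spec.b_absev * z_absev[j]
                + spec.b_cuenum * z_cuenum[j]
                + spec.b_norm * z_norm[j]
            )
            if a_k < 0:
                n_clipped += 1
                a_k = 0.0
            c_k = spec.b_same_diff * z_diff[j]
            sl = slice(onset, min(onset + n_env, n_samples))
            m = sl.stop - sl.start
            amp[sl] += a_k * env_burst[:m] + c_k * env_bi[:m]
            if spec.coupling == "lagged":
                gain[sl] += spec.coupling_gain * env_burst[:m] + (
                    spec.coupling_boost * is_diff[j]
                ) * env_couple[:m]

    neg = amp < 0
    n_clipped += int(neg.sum())
    amp[neg] = 0.0
    gain[gain < 0] = 0.0

    t = np.arange(n_samples) / fs
    # per-trial random carrier phase, constant within a trial block
    phase = np.zeros(n_samples)
    pos = lead
    for tr in trials:
        block = len(tr.cues) * soa_samp + gap_samp
        phase[pos - gap_samp // 2 : pos + block] = rng.uniform(0, 2 * np.pi)
        pos += block
    carrier = 2.0 * np.pi * spec.beta_freq * t + phase

    stn = (
        amp * np.sin(carrier)
        + spec.theta_amp * np.sin(2.0 * np.pi * spec.theta_freq * t)
        + powerlaw_noise(n_samples, spec.noise_exponent, rng, spec.noise_amp)
    )
    cortex = powerlaw_noise(n_samples, spec.noise_exponent, rng, spec.noise_amp)
    if spec.coupling == "lagged":
        cortex = cortex + gain * amp * np.sin(carrier + spec.coupling_lag)

    markers = pd.DataFrame(
        {"sample": onsets, "trial": marker_trial, "cue_index": marker_cue}
    )
    return ContinuousRecording(
        data=np.vstack([stn, cortex]),
        fs=fs,
        ch_names=["stn", "cortex"],
        markers=markers,
        meta={"n_amp_clipped": n_clipped, "spec": {"beta_freq": spec.beta_freq}},
    )
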