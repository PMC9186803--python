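"""Bayesian normalization and Shannon-surprise regressors.

Two cortical integrators Y_L and Y_R accumulate evidence for the two
responses, and a subthalamic normalization term is subtracted from both
after every cue:

    Y_L,t = (1-lam) Y_L,t-1 + (1 + omega SA_t) L_t - STN_{t-1}
    Y_R,t = (1-lam) Y_R,t-1 + (1 + omega SA_t) R_t - STN_{t-1}
    STN_t = ln(exp Y_L,t + exp Y_R,t)

with Y_L,0 = Y_R,0 = ln 0.5 (uniform prior) and L_t/R_t the 0/1 indicators
of cue identity.  The decay and bonus terms mirror whichever accumulator
model describes the participant, so that Y_R,t - Y_L,t reproduces that
model's decision variable exactly (the normalization term cancels in the
difference).  STN_t is the normalization regressor; its negative per-cue
increment under the exact Bayesian observer is the Shannon surprise
-ln P(cue_i | cue_1..i-1), a measure of global conflict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .accumulators import AccumulatorParams, compute_dv
from .task import TrialRecord, cues_to_array

__all__ = [
    "NormalizationTrace",
    "normalization_trace",
    "cue_surprise",
    "regressor_table",
    "REGRESSOR_COLUMNS",
]

LN_HALF = float(np.log(0.5))

REGRESSOR_COLUMNS = [
    "trial",
    "cue_index",
    "cue_identity_same",
    "abs_evidence",
    "cue_number",
    "bayes_norm",
    "surprise",
]


@dataclass
class NormalizationTrace:
    """Integrator and normalization values per cue (index 0 = first cue)."""

    y_left: np.ndarray
    y_right: np.ndarray
    stn: np.ndarray
    surprise: np.ndarray | None = None


def normalization_trace(cues: Sequence, params: AccumulatorParams) -> NormalizationTrace:
    """Run the coupled integrator/normalization recurrence over one trial.

    Overflow-safe: STN_t is evaluated with log-sum-exp.  Invariant (exact up
    to float rounding): y_right - y_left equals the decision variable of
    ``params`` at every cue.
    """
    s = cues_to_array(cues).astype(float)
    n = len(s)
    lam, omega = params.lam, params.omega
    yl = np.empty(n)
    yr = np.empty(n)
    stn = np.empty(n)
    prev_yl, prev_yr = LN_HALF, LN_HALF
    prev_stn = np.logaddexp(prev_yl, prev_yr)  # = 0 exactly
    prev_s = 0.0
    for t in range(n):
        sa = 1.0 if (t >= 1 and s[t] == prev_s) else 0.0
        bonus = 1.0 + omega * sa
        l_t = 1.0 if s[t] < 0 else 0.0
        r_t = 1.0 - l_t
        prev_yl = (1.0 - lam) * prev_yl + bonus * l_t - prev_stn
        prev_yr = (1.0 - lam) * prev_yr + bonus * r_t - prev_stn
        prev_stn = np.logaddexp(prev_yl, prev_yr)
        yl[t], yr[t], stn[t] = prev_yl, prev_yr, prev_stn
        prev_s = s[t]
    return NormalizationTrace(y_left=yl, y_right=yr, stn=stn)


def cue_surprise(cues: Sequence, validity: float) -> np.ndarray:
    """Shannon surprise -ln P(cue_i | cue_1..i-1) under the task statistics.

    The two directions are equally likely a priori and each cue is
    conditionally independent with the given validity v.  Writing q_i for
    the posterior probability that the true direction equals cue i (from
    Bayes rule over the previous i-1 cues), the predictive probability of
    cue i is q_i v + (1 - q_i)(1 - v).
    """
    v = float(validity)
    if not 0.5 < v < 1.0:
        raise ValueError(f"validity must lie in (0.5, 1), got {v}")
    s = cues_to_array(cues).astype(float)
    n = len(s)
    out = np.empty(n)
    log_v, log_u = np.log(v), np.log(1.0 - v)
    # log posterior weights for true = R and true = L
    lw_r = np.log(0.5)
    lw_l = np.log(0.5)
    for i in range(n):
        # posterior that true direction equals cue i's identity
        m = max(lw_r, lw_l)
        zr = np.exp(lw_r - m)
        zl = np.exp(lw_l - m)
        post_r = zr / (zr + zl)
        q = post_r if s[i] > 0 else 1.0 - post_r
        p_cue = q * v + (1.0 - q) * (1.0 - v)
        out[i] = -np.log(p_cue)
        if s[i] > 0:
            lw_r += log_v
            lw_l += log_u
        else:
            lw_r += log_u
            lw_l += log_v
    return out


def regressor_table(
    trials: Sequence[TrialRecord],
    params: AccumulatorParams,
    validity: float = 0.7,
) -> pd.DataFrame:
    """Per-cue regressor matrix for the neural GLM, one row per sampled cue.

    Columns: trial, cue_index (1-based), cue_identity_same (SA_t; NaN on the
    first cue where it is undefined), abs_evidence |DV_t|, cue_number t,
    bayes_norm STN_t, and surprise.  Raw values; z-scoring happens at
    design-matrix construction.
    """
    rows = []
    for tr in trials:
        trace = compute_dv(tr.cues, params)
        norm = normalization_trace(tr.cues, params)
        surp = cue_surprise(tr.cues, validity)
        n = len(tr.cues)
        for t in range(n):
            rows.append(
                {
                    "trial": tr.trial_id,
                    "cue_index": t + 1,
                    "cue_identity_same": float(trace.sa[t]) if t >= 1 else np.nan,
                    "abs_evidence": abs(trace.dv[t]),
                    "cue_number": t + 1,
                    "bayes_norm": norm.stn[t],
                    "surprise": surp[t],
                }
            )
    return pd.DataFrame(rows, columns=REGRESSOR_COLUMNS)
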