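"""Accumulator recurrences, likelihoods, fitting and model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from stnseq import (
    AccumulatorParams,
    AgentSpec,
    TaskConfig,
    choice_loglik,
    commitment_regression,
    compute_dv,
    fit_choice_model,
    select_model,
    simulate_behavior,
)
from stnseq.synth import simulate_choice_model_trials

cue_seqs = st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=12)


@pytest.mark.parametrize(
    "params, cues, expected",
    [
        (AccumulatorParams("M1"), ["R", "R", "L"], [1.0, 2.0, 1.0]),
        (AccumulatorParams("M2", lam=0.5), ["R", "R"], [1.0, 1.5]),
        (AccumulatorParams("M3", omega=0.5), ["R", "R"], [1.0, 2.5]),
        (AccumulatorParams("M4", lam=0.2, omega=0.5), ["R", "R"], [1.0, 2.3]),
    ],
)
def test_dv_recurrence_examples(params, cues, expected):
    np.testing.assert_allclose(compute_dv(cues, params).dv, expected, atol=1e-12)


def test_params_validation():
    with pytest.raises(ValueError):
        AccumulatorParams("M2", lam=1.5)
    with pytest.raises(ValueError):
        AccumulatorParams("M1", lam=0.3)  # lam pinned at 0 for M1
    with pytest.raises(ValueError):
        AccumulatorParams("M2", omega=0.5)  # omega pinned at 0 for M2


@given(cues=cue_seqs)
@settings(derandomize=True, max_examples=60)
def test_extended_models_reduce_to_perfect_integrator(cues):
    """With lam = omega = 0 all four recurrences are bitwise identical."""
    base = compute_dv(cues, AccumulatorParams("M1")).dv
    for mid in ("M2", "M3", "M4"):
        assert np.array_equal(compute_dv(cues, AccumulatorParams(mid)).dv, base)


@given(cues=cue_seqs)
@settings(derandomize=True, max_examples=60)
def test_dv_antisymmetric_under_relabelling(cues):
    params = AccumulatorParams("M4", lam=0.3, omega=0.6)
    flipped = [-c for c in cues]
    np.testing.assert_allclose(
        compute_dv(flipped, params).dv, -compute_dv(cues, params).dv, atol=1e-12
    )


def test_choice_loglik_uninformative(threshold_trials):
    params = AccumulatorParams("M1")
    n = sum(1 for t in threshold_trials if t.completed)
    ll = choice_loglik(threshold_trials, params, 0.0, 0.0)
    assert ll == pytest.approx(n * math.log(0.5), rel=1e-12)


def test_choice_loglik_matches_product_oracle(threshold_trials):
    """Brute-force per-trial Bernoulli product agrees to 1e-10 relative."""
    params = AccumulatorParams("M4", lam=0.2, omega=0.4)
    b0, b1 = 0.3, 1.2
    oracle = 0.0
    for t in threshold_trials:
        dv = compute_dv(t.cues, params).dv[-1]
        p_r = float(expit(b0 + b1 * dv))
        oracle += math.log(p_r if t.choice == 1 else 1.0 - p_r)
    assert choice_loglik(threshold_trials, params, b0, b1) == pytest.approx(oracle, rel=1e-10)


def test_choice_loglik_perfect_separation_limit(threshold_trials):
    """As beta1 grows with choices matching sign(DV), loglik approaches 0."""
    params = AccumulatorParams("M1")
    aligned = [t for t in threshold_trials if np.sign(compute_dv(t.cues, params).dv[-1]) == t.choice]
    ll = choice_loglik(aligned, params, 0.0, 50.0)
    assert -1e-10 < ll <= 0.0


def test_per_stimulus_likelihood_variant(threshold_trials):
    params = AccumulatorParams("M1")
    ll_final = choice_loglik(threshold_trials, params, 0.0, 0.0)
    ll_all = choice_loglik(threshold_trials, params, 0.0, 0.0, per_stimulus=True)
    n_stim = sum(t.n_sampled for t in threshold_trials)
    assert ll_all == pytest.approx(n_stim * math.log(0.5), rel=1e-12)
    assert ll_all < ll_final  # more Bernoulli terms


def test_beta1_recovery_from_m1_agent(task_cfg):
    """Slope recovered within +-0.3 from 2000 simulated choices."""
    est = []
    for seed in (0, 1, 2):
        tr = simulate_choice_model_trials(
            task_cfg, AccumulatorParams("M1"), 0.0, 2.0, 2000, seed
        )
        est.append(fit_choice_model(tr, "M1").beta1)
    assert abs(np.mean(est) - 2.0) < 0.3


def test_null_slope_covered_by_confidence_interval(task_cfg, rng):
    """Choices independent of cues leave beta1 indistinguishable from 0."""
    tr = simulate_choice_model_trials(task_cfg, AccumulatorParams("M1"), 0.0, 2.0, 1500, 5)
    for t in tr:
        t.choice = int(rng.choice([-1, 1]))
    fit = fit_choice_model(tr, "M1")
    assert abs(fit.beta1) < 1.96 * fit.se_beta1 + 0.05


def test_bic_definition_and_ranking(task_cfg):
    tr = simulate_choice_model_trials(task_cfg, AccumulatorParams("M1"), 0.0, 2.0, 1000, 9)
    fits = select_model(tr)
    assert [f.bic for f in fits] == sorted(f.bic for f in fits)
    for f in fits:
        assert f.bic == pytest.approx(f.k * math.log(f.n_obs) - 2 * f.loglik, rel=1e-12)
    # equal fit quality: the BIC penalty favors the low-k generating model
    assert fits[0].params.model_id == "M1"


def test_model_selection_recovers_bonus_model(task_cfg):
    tr = simulate_choice_model_trials(
        task_cfg, AccumulatorParams("M3", omega=0.8), 0.0, 2.0, 4000, 17
    )
    fits = select_model(tr)
    assert fits[0].params.model_id in ("M3", "M4")


def test_fit_requires_enough_trials(task_cfg):
    tr = simulate_choice_model_trials(task_cfg, AccumulatorParams("M1"), 0.0, 2.0, 10, 3)
    with pytest.raises(ValueError):
        fit_choice_model(tr, "M1")


class TestCommitmentRegression:
    def test_threshold_stopper_is_evidence_driven(self, task_cfg):
        hits = 0
        for seed in (0, 1, 2):
            tr = simulate_behavior(task_cfg, AgentSpec(threshold=2.0), 400, seed)
            fit = commitment_regression(tr)
            assert fit.p_evidence < 0.05
            hits += fit.classification == "evidence_only"
        assert hits >= 2

    def test_cue_insensitive_stopper_is_null(self, task_cfg):
        agent = AgentSpec(
            stop_rule="logistic", stop_beta=(-1.0, 0.0, 0.0), choice_policy="random"
        )
        neither = 0
        for seed in range(6):
            tr = simulate_behavior(task_cfg, agent, 300, 100 + seed)
            neither += commitment_regression(tr).classification == "neither"
        assert neither >= 5

    def test_repetition_stopper_flags_same_factor(self, task_cfg):
        agent = AgentSpec(stop_rule="logistic", stop_beta=(-8.0, 0.0, 12.0))
        tr = simulate_behavior(task_cfg, agent, 400, 5)
        fit = commitment_regression(tr)
        assert fit.p_same < 0.05
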