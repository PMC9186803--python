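import numpy as np
import pytest

from stnseq import (
    AccumulatorParams,
    AgentSpec,
    NeuralSimSpec,
    TaskConfig,
    continuous_band_power,
    epoch_power,
    highpass_power,
    regressor_table,
    simulate_behavior,
    simulate_recording,
)


@pytest.fixture(scope="session")
def task_cfg():
    return TaskConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def threshold_trials(task_cfg):
    """400 trials from the default evidence-threshold agent."""
    return simulate_behavior(task_cfg, AgentSpec(), 400, 7)


@pytest.fixture(scope="session")
def demo_regressors(task_cfg, threshold_trials):
    return regressor_table(threshold_trials[:48], AccumulatorParams("M1"), task_cfg.validity)


@pytest.fixture(scope="session")
def demo_recording(task_cfg, threshold_trials, demo_regressors):
    """Small recording with all generator effects at their defaults."""
    rec = simulate_recording(threshold_trials[:48], demo_regressors, NeuralSimSpec(), 11)
    return rec


@pytest.fixture(scope="session")
def demo_beta_epochs(demo_recording):
    pts = highpass_power(continuous_band_power(demo_recording, "beta"))
    return epoch_power(pts, demo_recording.markers, channel="stn")
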