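import numpy as np
import pytest

from asymrpe import rl, synth, task


@pytest.fixture(scope="session")
def agent():
    return task.AgentConfig(timing_sd=0.06)


@pytest.fixture(scope="session")
def session_trials(agent):
    """One standard 4-block session of a stationary timer."""
    return task.run_session(task.TaskConfig(), agent, seed=11)


@pytest.fixture(scope="session")
def augmented_session(session_trials):
    """Cleaned, RL-augmented trial frame for the standard session."""
    kept = task.reject_trials(session_trials)
    return rl.augment_trials(task.trials_to_frame(kept))


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed-category neural cohort used across encoding tests."""
    cfg = synth.CohortConfig(n_subjects=3, channels_per_region=3)
    return synth.generate_cohort(cfg, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
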