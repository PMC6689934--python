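import numpy as np
import pytest

import twostep_credit as tc
from twostep_credit.task import COMMON_STATE, STATE_FRACTALS, key_for


@pytest.fixture(scope="session")
def task_config():
    return tc.TaskConfig(n_trials=300)


@pytest.fixture(scope="session")
def model2_params():
    return tc.AgentParams(
        model_id=2, alpha1=0.45, lambda1=0.6, alpha2=0.45, lambda2=0.5,
        w1=0.5, w2=0.3, beta=4.0, persev_fractal=0.2, persev_key=0.1,
    )


@pytest.fixture(scope="session")
def session_records(task_config, model2_params):
    """One simulated 300-trial session from the key-value model."""
    sched = tc.make_reward_schedule(task_config, 7)
    return tc.simulate_agent(2, model2_params, task_config, sched, 42, "S1")


@pytest.fixture(scope="session")
def small_cohort():
    """12 heterogeneous Model 2 subjects x 150 trials, with ground truth."""
    spec = tc.default_population(2, n_subjects=12, n_trials=150, seed=5)
    records, truth = tc.generate_cohort(spec, tc.TaskConfig())
    return records, truth


def make_trial(
    s1_choice="A",
    s1_mapping="A-left",
    transition="common",
    s2_choice=None,
    s2_mapping=None,
    reward=1,
    subject_id="S1",
    trial=0,
):
    """Build a structurally valid trial from choices and mappings."""
    common = COMMON_STATE[s1_choice]
    state = common if transition == "common" else ("s3" if common == "s2" else "s2")
    pair = STATE_FRACTALS[state]
    s2_choice = s2_choice or pair[0]
    s2_mapping = s2_mapping or f"{pair[0]}-left"
    return tc.TrialRecord(
        subject_id=subject_id,
        trial=trial,
        s1_choice=s1_choice,
        s1_mapping=s1_mapping,
        s1_key=key_for(s1_choice, s1_mapping),
        transition=transition,
        s2_state=state,
        s2_choice=s2_choice,
        s2_mapping=s2_mapping,
        s2_key=key_for(s2_choice, s2_mapping),
        reward=reward,
    )
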