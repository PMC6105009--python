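import numpy as np
import pandas as pd
import pytest

from relsal.hgf import LearnParams
from relsal.inference import ModelSpec
from relsal.response import RespParams
from relsal.stats import preprocess_rts
from relsal.task import TaskConfig, TaskSequence, generate_task, simulate_subject


@pytest.fixture(scope="session")
def default_task():
    return generate_task(TaskConfig(seed=1))


@pytest.fixture(scope="session")
def full_model():
    return ModelSpec("2HGF", "RelPE+IrrelBias")


@pytest.fixture(scope="session")
def gen_params():
    learn = LearnParams(omega=-2.0, sigma2_0=0.05, variant="2HGF")
    resp = RespParams(
        beta0=6.25, beta1=0.2, beta2=0.05, beta3=0.0, beta4=0.03, beta5=0.01,
        beta6=0.07, zeta=0.04, variant="RelPE+IrrelBias",
    )
    return learn, resp


@pytest.fixture(scope="session")
def sim_behavior(default_task, full_model, gen_params):
    learn, resp = gen_params
    return preprocess_rts(
        simulate_subject(default_task, full_model, learn, resp, seed=3)
    )


def make_task(trials: pd.DataFrame, config: TaskConfig | None = None) -> TaskSequence:
    """Build a TaskSequence around a hand-constructed trial table (n divisible by 4)."""
    n = len(trials)
    cfg = config if config is not None else TaskConfig(
        n_trials=n, block_length=n, switch_trial=n
    )
    schedule = pd.DataFrame(
        [
            {
                "block": 1,
                "first_trial": 1,
                "relevant_dimension": trials["relevant_dimension"].iloc[0],
                "rewarded_manifestation": trials["rewarded_manifestation"].iloc[0],
            }
        ]
    )
    return TaskSequence(config=cfg, trials=trials, schedule=schedule)
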