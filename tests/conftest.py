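import numpy as np
import pandas as pd
import pytest

from sp5c.agent import StochasticAgent, scripted_agent
from sp5c.engine import run_session
from sp5c.protocol import build_preset


@pytest.fixture(scope="session")
def ua_config():
    return build_preset("UA")


@pytest.fixture(scope="session")
def tr_config():
    return build_preset("TR")


@pytest.fixture(scope="session")
def perfect_training_log(ua_config):
    """Full ladder traversal by the always-correct scripted responder."""
    return run_session(ua_config, scripted_agent("perfect"), seed=11,
                       horizon_s=30 * 86_400.0)


@pytest.fixture(scope="session")
def stochastic_training_log(tr_config):
    """One stochastic training run under the time-restricted protocol."""
    return run_session(tr_config, StochasticAgent(), seed=23,
                       horizon_s=60 * 86_400.0)


def random_trial_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Synthetic trial table with all four outcomes and noisy latencies."""
    outcomes = rng.choice(
        ["correct", "incorrect", "omission", "premature"],
        size=n, p=[0.6, 0.15, 0.2, 0.05],
    )
    correct = outcomes == "correct"
    return pd.DataFrame({
        "trial_index": np.arange(n),
        "stage_id": 8,
        "t_start": np.sort(rng.uniform(0, 9000.0, size=n)),
        "outcome": outcomes,
        "hole": rng.integers(1, 6, size=n),
        "iti_used": 5.0,
        "sd_used": 1.0,
        "correct_latency": np.where(correct, rng.lognormal(0.2, 0.4, n), np.nan),
        "magazine_latency": np.where(correct, rng.lognormal(0.6, 0.9, n), np.nan),
        "in_dark_phase": rng.random(n) < 0.9,
        "incomplete": False,
    })
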