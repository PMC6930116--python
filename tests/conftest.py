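import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pursuit3d.simulator import run_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort_200():
    """The default 200-trajectory cohort shared by the model-comparison tests.

    Four controllers on identical trajectories/encounters/schedules.
    """
    kinds = ["random_choice", "regression_position", "regression_velocity",
             "ideal_velocity"]
    metrics, post = run_cohort(kinds, n_trajectories=200, seed=0)
    return kinds, metrics, post


def strike_counts(metrics):
    return {k: int(((metrics.model == k) & (metrics.outcome == "strike")).sum())
            for k in metrics.model.unique()}
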