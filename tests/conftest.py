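import numpy as np
import pytest

from oaad.streaming import SessionPlan, run_online_session
from oaad.synthetic import ForwardModel, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def experiment_session():
    """Simulation-style session: 15 construction + 12 fixed + 4 switching test trials."""
    plan = SessionPlan(n_construction=15, n_test_fixed=12, n_test_switching=4)
    forward = ForwardModel.default(rng=11)
    return generate_session(plan, forward, rng_seed=11)


@pytest.fixture(scope="session")
def experiment_result(experiment_session):
    return run_online_session(experiment_session.plan, experiment_session.trials)
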