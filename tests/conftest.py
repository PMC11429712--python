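import numpy as np
import pytest

import policycomp as pc


@pytest.fixture(scope="session")
def task():
    return pc.make_task()


@pytest.fixture(scope="session")
def q_task(task):
    return pc.q_mean(task)


@pytest.fixture(scope="session")
def state_probs(task):
    return np.asarray(task.state_probs)


@pytest.fixture(scope="session")
def default_frontier(q_task, state_probs):
    return pc.frontier(q_task, state_probs)


@pytest.fixture(scope="session")
def small_dataset(task):
    """Six short synthetic sessions with responses (fast shared fixture)."""
    return pc.generate_dataset(n_sessions=6, n_trials=300, seed=11, task=task)


def random_policies(n, rng, n_states=9, n_actions=2, state_probs=None):
    """Random conditional policies with self-consistent marginals.

    Pass ``state_probs`` to hold P(s) fixed (required when comparing against
    a frontier or objective computed for a specific state distribution).
    """
    for _ in range(n):
        p_s = rng.dirichlet(np.ones(n_states)) if state_probs is None \
            else np.asarray(state_probs)
        cond = rng.dirichlet(np.ones(n_actions), size=n_states)
        yield pc.Policy(p_s, cond, p_s @ cond)
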