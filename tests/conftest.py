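import pytest

from relbandit.cogmodel import AgentParams, ModelSpec
from relbandit.task_designs import (
    ContextSpec,
    OptionSpec,
    RewardModel,
    TaskSpec,
    load_task_spec,
)


@pytest.fixture(scope="session")
def v2023():
    return load_task_spec("V2023")


@pytest.fixture(scope="session")
def hw2023a():
    return load_task_spec("HW2023a")


@pytest.fixture(scope="session")
def bp2023():
    return load_task_spec("BP2023")


@pytest.fixture(scope="session")
def rel_full():
    """Hybrid encoding, two learning rates, two inverse temperatures."""
    return ModelSpec(relative_encoding=True, n_learning_rates=2, n_betas=2)


@pytest.fixture(scope="session")
def abs_simple():
    return ModelSpec(relative_encoding=False, n_learning_rates=1, n_betas=1)


@pytest.fixture(scope="session")
def rel_full_agent(rel_full):
    return AgentParams.create(rel_full, omega=0.5, alpha=0.5, alpha_dis=0.15,
                              beta=10.0, beta_transfer=6.0, position_bias=0.5)


def two_option_task(reward_a, reward_b, n_trials=10, reps=1, name="toy"):
    """Minimal single-context task used across test modules."""
    return TaskSpec(
        name=name,
        options=(OptionSpec("a", reward_a), OptionSpec("b", reward_b)),
        contexts=(ContextSpec("c1", ("a", "b"), n_trials),),
        transfer_reps=reps,
    )


@pytest.fixture(scope="session")
def equal_options_task():
    """Two identical Bernoulli options in one context (all ties everywhere)."""
    r = RewardModel(kind="bernoulli", win_prob=0.5, hi_value=1.0, lo_value=0.0)
    return two_option_task(r, r)
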