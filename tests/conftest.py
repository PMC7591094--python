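import numpy as np
import pytest

from abstraxion.mdp_core import TabularMDP


def random_mdp(
    n_states: int,
    n_actions: int,
    rng: np.random.Generator,
    discount: float = 0.9,
    reward_scale: float = 1.0,
) -> TabularMDP:
    """Dense random MDP: Dirichlet transition rows, uniform rewards."""
    p = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
    r = reward_scale * rng.random((n_states, n_actions, n_states))
    return TabularMDP(transition=p, reward=r, discount=discount)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def column_world():
    from abstraxion.task_suite import make_column_world

    return make_column_world()
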