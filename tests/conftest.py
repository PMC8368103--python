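import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from linrl import SolverConfig, build_gridworld, build_task

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def config():
    return SolverConfig()


@pytest.fixture
def chain_task():
    """s -> t, one forced step of cost 1, goal reward 0."""
    return build_task({"s": ["t"]}, {"t": 0.0}, -1.0)


@pytest.fixture
def two_chain_task():
    """s1 -> s2 -> t, cost 1 each."""
    return build_task({"s1": ["s2"], "s2": ["t"]}, {"t": 0.0}, -1.0)


@pytest.fixture
def two_option_task():
    """One choice state with terminal options A (reward 1) and B (reward 0)."""
    return build_task({"C": ["A", "B"]}, {"A": 1.0, "B": 0.0}, 0.0)


def make_random_dag_task(rng, n_nonterminal=12, n_terminal=3):
    """Random absorbing DAG with distinct nonzero integer rewards."""
    n = n_nonterminal + n_terminal
    adj = {}
    for i in range(n_nonterminal):
        later = list(range(i + 1, n))
        k = min(len(later), int(rng.integers(2, 4)))
        adj[i] = [int(s) for s in rng.choice(later, size=k, replace=False)]
    rew = rng.permutation(np.arange(-n_nonterminal, n_terminal))
    rew = rew + np.where(rew >= 0, 1, 0)  # distinct integers, none zero
    nonterm = {i: float(rew[i]) for i in range(n_nonterminal)}
    term = {j: float(rew[j]) for j in range(n_nonterminal, n)}
    return build_task(adj, term, nonterm)


def make_random_grid(rng, width=6, height=6, n_blocked=6, terminal_reward=5.0):
    """Connected random maze with one terminal in a free corner cell."""
    from linrl.experiments import random_maze

    maze = random_maze(width, height, n_blocked, rng)
    goal = maze.cells[int(rng.integers(len(maze.cells)))]
    return build_gridworld(
        width=width, height=height, blocked=maze.blocked, cell_cost=-1.0,
        terminal_cells={goal: terminal_reward},
    )


@pytest.fixture
def random_dag_factory():
    return make_random_dag_task


@pytest.fixture
def random_grid_factory():
    return make_random_grid
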