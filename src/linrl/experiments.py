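"""Seeded behavioral simulation studies and baseline agents.

Each ``run_*`` function is a pure function of its parameters and seed and
returns an :class:`ExperimentResult` with a tidy metrics table.  All
linear-RL agents in this module go through the single solver in
:mod:`linrl.linear_solver`; baselines (depth-pruned model-based search,
the successor representation, exact value iteration / expectimax) are
independent implementations used for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .default_learning import DefaultPolicy, delta_update, refresh_dr
from .linear_solver import compute_dr, solve_values
from .replanning import (
    apply_transition_change,
    blocked_edge_rows,
    greedy_path,
    plan_to_goal,
)
from .stochastic_control import (
    ActionModel,
    StochasticTask,
    expectimax_oracle,
    marginal_dynamics,
    project_policy,
    stochastic_policy,
)
from .task_model import GridWorld, SolverConfig, TaskError, TaskGraph, build_gridworld, build_task

__all__ = [
    "ExperimentResult",
    "TreeTask",
    "random_tree_task",
    "pruned_depth_agent",
    "linear_rl_tree_agent",
    "sr_agent",
    "absorption_probabilities",
    "expected_steps",
    "run_tree_benchmark",
    "run_shortest_path_suite",
    "run_latent_learning",
    "run_policy_revaluation",
    "run_detour",
    "run_two_step",
    "run_counterexample",
    "run_habit_choice",
    "run_habit_rooms",
    "run_stroop",
    "run_pit",
    "EXPERIMENTS",
    "run_experiment",
]


@dataclass
class ExperimentResult:
    """Tidy, seeded output of one simulation experiment."""

    name: str
    seed: int | None
    params: dict
    metrics: pd.DataFrame


def _tidy(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["condition", "agent", "metric", "value", "replicate"])


# ---------------------------------------------------------------------------
# Generic policy-evaluation helpers
# ---------------------------------------------------------------------------

def absorption_probabilities(task: TaskGraph, policy: np.ndarray) -> np.ndarray:
    """P(absorb at each terminal | start) for every nonterminal start."""
    nt, term = task.nonterminal, task.terminal
    Pi_NN = policy[np.ix_(nt, nt)]
    Pi_NT = policy[np.ix_(nt, term)]
    return np.linalg.solve(np.eye(nt.size) - Pi_NN, Pi_NT)

def expected_steps(task: TaskGraph, policy: np.ndarray, start) -> float:
    """Expected number of steps to absorption from ``start`` under π."""
    nt = task.nonterminal
    Pi_NN = policy[np.ix_(nt, nt)]
    t = np.linalg.solve(np.eye(nt.size) - Pi_NN, np.ones(nt.size))
    si = int(start) if isinstance(start, (int, np.integer)) else task.index(start)
    return float(t[np.searchsorted(nt, si)])

def expected_visits(task: TaskGraph, policy: np.ndarray, start) -> np.ndarray:
    """Expected visit counts to each nonterminal state before absorption."""
    nt = task.nonterminal
    Pi_NN = policy[np.ix_(nt, nt)]
    si = int(start) if isinstance(start, (int, np.integer)) else task.index(start)
    e = np.zeros(nt.size)
    e[np.searchsorted(nt, si)] = 1.0
    return np.linalg.solve(np.eye(nt.size) - Pi_NN.T, e)


# ---------------------------------------------------------------------------
# Decision trees: linear RL vs depth-pruned model-based search
# ---------------------------------------------------------------------------

@dataclass
class TreeTask:
    """A complete binary decision tree with per-state costs.

    Internal nodes are heap-ordered ``0 .. 2^levels - 2`` (root 0), leaves
    follow; ``costs`` are positive and enter the task graph as negative
    rewards.  The objective is the cheapest root-to-leaf path.
    """

    levels: int
    costs: np.ndarray
    task: TaskGraph

    @property
    def n_internal(self) -> int:
        return 2 ** self.levels - 1

    def children(self, i: int):
        if i >= self.n_internal:
            raise TaskError("tree required: leaves have no children")
        return 2 * i + 1, 2 * i + 2

    def is_leaf(self, i: int) -> bool:
        return i >= self.n_internal


def random_tree_task(levels: int = 7, cost_range=(0.0, 10.0), rng=None) -> TreeTask:
    """A complete binary tree with i.i.d. uniform costs at every state."""
    rng = np.random.default_rng(rng)
    n_int = 2 ** levels - 1
    n = n_int + 2 ** levels
    costs = rng.uniform(cost_range[0], cost_range[1], size=n)
    adjacency = {i: [2 * i + 1, 2 * i + 2] for i in range(n_int)}
    terminal = {i: -costs[i] for i in range(n_int, n)}
    nonterm = {i: -costs[i] for i in range(n_int)}
    task = build_task(adjacency, terminal, nonterm)
    return TreeTask(levels=levels, costs=costs, task=task)


def _random_walk_cost(tree: TreeTask) -> np.ndarray:
    """Expected cost-to-go under the uniform random walk, all nodes."""
    n = tree.costs.size
    v = np.zeros(n)
    for i in range(n - 1, -1, -1):
        if tree.is_leaf(i):
            v[i] = tree.costs[i]
        else:
            a, b = tree.children(i)
            v[i] = tree.costs[i] + 0.5 * (v[a] + v[b])
    return v


def _optimal_cost(tree: TreeTask) -> float:
    """Cheapest root-leaf path cost, summed exactly as realized costs are."""
    n = tree.costs.size
    v = np.zeros(n)
    for i in range(n - 1, -1, -1):
        if tree.is_leaf(i):
            v[i] = tree.costs[i]
        else:
            a, b = tree.children(i)
            v[i] = tree.costs[i] + min(v[a], v[b])
    path = [0]
    cur = 0
    while not tree.is_leaf(cur):
        a, b = tree.children(cur)
        cur = a if v[a] <= v[b] else b
        path.append(cur)
    return float(tree.costs[path].sum())


@dataclass
class TreeAgentRun:
    root_choice: int
    path: list
    realized_cost: float
    extra_cost: float


def pruned_depth_agent(tree: TreeTask, depth: int) -> TreeAgentRun:
    """Model-based agent that searches ``depth`` levels, then substitutes
    the exact random-walk average cost of the remaining subtree.

    At the full tree depth this is exact; at depth 1 the leaf evaluation is
    the value under the uniform random walk (the on-policy successor
    representation for that policy).  The agent replans at every step.
    """
    if not 1 <= depth <= tree.levels:
        raise TaskError(f"depth must lie in [1, {tree.levels}]")
    v_rw = _random_walk_cost(tree)
    costs = tree.costs

    def evaluate(i: int, d: int) -> float:
        if tree.is_leaf(i):
            return costs[i]
        if d == 0:
            return v_rw[i]
        a, b = tree.children(i)
        return costs[i] + min(evaluate(a, d - 1), evaluate(b, d - 1))

    path = [0]
    cur = 0
    while not tree.is_leaf(cur):
        a, b = tree.children(cur)
        cur = a if evaluate(a, depth - 1) <= evaluate(b, depth - 1) else b
        path.append(cur)
    realized = float(costs[path].sum())
    extra = realized - _optimal_cost(tree)
    return TreeAgentRun(root_choice=path[1], path=path, realized_cost=realized, extra_cost=extra)


def linear_rl_tree_agent(tree: TreeTask, config: SolverConfig = SolverConfig()) -> TreeAgentRun:
    """Greedy descent on the KL-regularized optimal values (uniform default)."""
    sol = solve_values(tree.task, None, config)
    path = [0]
    cur = 0
    while not tree.is_leaf(cur):
        a, b = tree.children(cur)
        cur = a if sol.v_all[a] >= sol.v_all[b] else b
        path.append(cur)
    realized = float(tree.costs[path].sum())
    extra = realized - _optimal_cost(tree)
    return TreeAgentRun(root_choice=path[1], path=path, realized_cost=realized, extra_cost=extra)


def run_tree_benchmark(
    levels: int = 7,
    cost_range=(0.0, 10.0),
    reps: int = 100,
    seed: int = 0,
    lam: float = 1.0,
) -> ExperimentResult:
    """Average extra cost (relative to the optimum) of linear RL and of
    depth-pruned model-based agents D1..D(levels) over random trees."""
    rng = np.random.default_rng(seed)
    config = SolverConfig(lam=lam)
    rows = []
    for rep in range(reps):
        tree = random_tree_task(levels, cost_range, rng)
        rows.append(("tree", "LRL", "extra_cost", linear_rl_tree_agent(tree, config).extra_cost, rep))
        for d in range(1, levels + 1):
            rows.append(("tree", f"D{d}", "extra_cost", pruned_depth_agent(tree, d).extra_cost, rep))
    return ExperimentResult(
        name="tree_benchmark",
        seed=seed,
        params={"levels": levels, "cost_range": tuple(cost_range), "reps": reps, "lam": lam},
        metrics=_tidy(rows),
    )


# ---------------------------------------------------------------------------
# Successor-representation baseline
# ---------------------------------------------------------------------------

@dataclass
class SRAgent:
    """On-policy successor representation and the values it implies."""

    S: np.ndarray
    v_all: np.ndarray
    greedy: np.ndarray


def sr_agent(task: TaskGraph, training_policy: np.ndarray) -> SRAgent:
    """Values from the successor representation of a fixed training policy.

    ``S = (I - Π_NN)^{-1}`` caches expected future visits under the policy;
    values are ``S @ (r_N + Π_NT r_T)`` and choices are greedy one-step
    lookups on them.  Because S is tied to the training policy, it keeps
    implying that policy's downstream choices after rewards change.
    """
    nt, term = task.nonterminal, task.terminal
    Pi_NN = training_policy[np.ix_(nt, nt)]
    if _spectral_radius_le(Pi_NN):
        raise TaskError("SR undefined: training policy is not absorbing")
    S = np.linalg.inv(np.eye(nt.size) - Pi_NN)
    r_exp = task.r_N + training_policy[np.ix_(nt, term)] @ task.r_T
    v = S @ r_exp
    v_all = np.where(task.terminal_mask, task.r_A, 0.0)
    v_all[nt] = v
    greedy = np.full(task.n_states, -1, dtype=int)
    for i in nt:
        succ = task.successors(int(i))
        greedy[i] = int(succ[np.argmax(v_all[succ])])
    return SRAgent(S=S, v_all=v_all, greedy=greedy)


def _spectral_radius_le(Pi_NN: np.ndarray) -> bool:
    if Pi_NN.size == 0:
        return False
    return bool(np.max(np.abs(np.linalg.eigvals(Pi_NN))) >= 1.0 - 1e-10)


# ---------------------------------------------------------------------------
# Maze shortest paths from one cached DR
# ---------------------------------------------------------------------------

def random_maze(
    width: int = 10,
    height: int = 10,
    n_blocked: int = 20,
    rng=None,
    cell_cost: float = -1.0,
) -> GridWorld:
    """A random maze whose free region is connected (blocked cells are
    resampled until connectivity holds); built with no terminal states."""
    rng = np.random.default_rng(rng)
    cells = [(r, c) for r in range(height) for c in range(width)]
    for _ in range(10_000):
        idx = rng.choice(len(cells), size=n_blocked, replace=False)
        blocked = {cells[i] for i in idx}
        free = [c for c in cells if c not in blocked]
        g = nx.Graph()
        g.add_nodes_from(free)
        for r, c in free:
            for nb in ((r + 1, c), (r, c + 1)):
                if nb in g:
                    g.add_edge((r, c), nb)
        if nx.is_connected(g):
            return build_gridworld(
                width=width, height=height, blocked=blocked, cell_cost=cell_cost,
                terminal_cells={}, validate=False,
            )
    raise TaskError("could not sample a connected maze")


def _bfs_lengths(grid: GridWorld) -> dict:
    g = nx.Graph()
    g.add_nodes_from(range(grid.task.n_states))
    rows, cols = np.nonzero(grid.task.T > 0)
    g.add_edges_from((int(a), int(b)) for a, b in zip(rows, cols) if a != b)
    return dict(nx.all_pairs_shortest_path_length(g))


def run_shortest_path_suite(
    width: int = 10,
    height: int = 10,
    n_blocked: int = 20,
    seed: int = 0,
    lam: float = 1.0,
) -> ExperimentResult:
    """Fraction of ordered state pairs whose greedy linear-RL path length
    equals the breadth-first shortest-path length.

    One DR is computed for the goal-free maze (uniform cost 1); each goal is
    then added by a rank-1 identity update and paths are read greedily from
    the resulting values.
    """
    config = SolverConfig(lam=lam)
    grid = random_maze(width, height, n_blocked, np.random.default_rng(seed))
    task = grid.task
    dr = compute_dr(task, config)
    bfs = _bfs_lengths(grid)
    n = task.n_states
    matched = 0
    total = 0
    for goal in range(n):
        plan = plan_to_goal(dr, task, goal, goal_reward=1.0, config=config)
        for start in range(n):
            if start == goal:
                continue
            total += 1
            path = greedy_path(plan.task, plan.v_all, start, goal)
            if len(path) - 1 == bfs[start][goal]:
                matched += 1
    frac = matched / total
    rows = [
        ("maze", "LRL", "fraction_optimal", frac, 0),
        ("maze", "LRL", "n_pairs", float(total), 0),
    ]
    return ExperimentResult(
        name="shortest_path_suite",
        seed=seed,
        params={"width": width, "height": height, "n_blocked": n_blocked, "lam": lam},
        metrics=_tidy(rows),
    )


# ---------------------------------------------------------------------------
# Replanning: latent learning, policy revaluation, detour
# ---------------------------------------------------------------------------

_LATENT_LAYOUT = """\
A.....B
###.###
###.###
###.###
"""

def run_latent_learning(seed: int = 0, lam: float = 1.0, box_reward: float = 5.0,
                        devalued_reward: float = -5.0) -> ExperimentResult:
    """Goal devaluation in a two-end-box maze.

    Training: both end boxes carry ``box_reward`` (cost 1 per step), and the
    DR is computed once.  Test: the left box is devalued; values are
    recomputed from the unchanged DR and choice reallocates to the right
    box on the very first test trial.
    """
    config = SolverConfig(lam=lam)
    grid = build_gridworld(_LATENT_LAYOUT, cell_cost=-1.0,
                           terminal_cells={"A": box_reward, "B": box_reward})
    task = grid.task
    start = grid.state_of((3, 3))
    dr = compute_dr(task, config)
    rows = []
    left, right = grid.state_of((0, 0)), grid.state_of((0, 6))
    for condition, rewards in (
        ("train", {}),
        ("test", {(0, 0): devalued_reward}),
    ):
        t = task.with_terminal_rewards(rewards) if rewards else task
        sol = solve_values(t, dr, config)  # same DR in both phases
        absorb = absorption_probabilities(t, sol.policy)
        k = int(np.searchsorted(t.nonterminal, start))
        tcols = list(t.terminal)
        rows.append((condition, "LRL", "p_left", float(absorb[k, tcols.index(left)]), 0))
        rows.append((condition, "LRL", "p_right", float(absorb[k, tcols.index(right)]), 0))
    return ExperimentResult(
        name="latent_learning",
        seed=seed,
        params={"lam": lam, "box_reward": box_reward, "devalued_reward": devalued_reward},
        metrics=_tidy(rows),
    )


def _revaluation_task(rewards: dict) -> TaskGraph:
    adjacency = {1: [2, 3], 2: ["T1", "T2"], 3: ["T3"]}
    return build_task(adjacency, rewards, nonterminal_rewards=0.0)


def run_policy_revaluation(
    seed: int = 0,
    lam: float = 1.0,
    train_rewards=(0.0, 5.0, 10.0),
    revalued_t1: float = 40.0,
) -> ExperimentResult:
    """Multi-stage reward revaluation that defeats the on-policy SR.

    Training rewards make state 3 preferred from state 1; raising the
    previously worst terminal reverses the preference at state 1, which
    requires re-optimizing the downstream choice at state 2.  Linear RL
    solves this with its training-phase representation (for a uniform
    default and for the optimized training policy as default); the SR under
    the training policy does not reverse.
    """
    config = SolverConfig(lam=lam)
    t1, t2, t3 = train_rewards
    train = _revaluation_task({"T1": t1, "T2": t2, "T3": t3})
    dr = compute_dr(train, config)
    sol_train = solve_values(train, dr, config)
    test = train.with_terminal_rewards({"T1": revalued_t1})
    sol_test = solve_values(test, dr, config)  # unchanged DR

    i1, i2, i3 = train.index(1), train.index(2), train.index(3)
    rows = [
        ("train", "LRL", "p_state3", float(sol_train.policy[i1, i3]), 0),
        ("test", "LRL", "p_state2", float(sol_test.policy[i1, i2]), 0),
    ]

    # optimized training policy as the default: the reversal is insensitive
    # to the default policy
    opt_default = TaskGraph.from_matrix(
        train.state_ids, train.terminal_mask, sol_train.policy, train.r_A
    )
    sol_opt = solve_values(opt_default.with_terminal_rewards({"T1": revalued_t1}), None, config)
    rows.append(("test", "LRL_optimized_default", "p_state2",
                 float(sol_opt.policy[i1, i2]), 0))

    # SR under the training policy: greedy test choice at state 1
    sr = sr_agent(test, sol_train.policy)
    rows.append(("test", "SR", "chooses_state2", float(sr.greedy[i1] == i2), 0))
    rows.append(("test", "SR", "chooses_state3", float(sr.greedy[i1] == i3), 0))
    return ExperimentResult(
        name="policy_revaluation",
        seed=seed,
        params={"lam": lam, "train_rewards": tuple(train_rewards), "revalued_t1": revalued_t1},
        metrics=_tidy(rows),
    )


_DETOUR_LAYOUT = """\
..G
.#.
.#.
.#.
...
"""

def run_detour(seed: int = 0, lam: float = 1.0, goal_reward: float = 5.0) -> ExperimentResult:
    """Barrier insertion: replan with a low-rank DR update only.

    Pre-barrier the straight corridor is taken; walling off the corridor's
    top edge changes a single default row, and folding that rank-1
    correction into the cached DR reroutes the greedy path through the
    left corridor.
    """
    config = SolverConfig(lam=lam)
    grid = build_gridworld(_DETOUR_LAYOUT, cell_cost=-1.0, terminal_cells={"G": goal_reward})
    task = grid.task
    start = grid.state_of((4, 2))
    goal = grid.state_of((0, 2))
    dr = compute_dr(task, config)
    sol = solve_values(task, dr, config)
    pre_path = greedy_path(task, sol, start, goal)

    rows_changed = blocked_edge_rows(grid, [((1, 2), (0, 2))])
    task2, dr2, upd = apply_transition_change(dr, task, rows_changed, config=config)
    sol2 = solve_values(task2, dr2, config)
    post_path = greedy_path(task2, sol2, start, goal)

    left_cell = grid.state_of((4, 1))
    rows = [
        ("pre", "LRL", "path_length", float(len(pre_path) - 1), 0),
        ("pre", "LRL", "went_left", float(pre_path[1] == left_cell), 0),
        ("post", "LRL", "path_length", float(len(post_path) - 1), 0),
        ("post", "LRL", "went_left", float(post_path[1] == left_cell), 0),
        ("post", "LRL", "barrier_rank", float(np.linalg.matrix_rank(upd.B, tol=1e-10)), 0),
    ]
    return ExperimentResult(
        name="detour",
        seed=seed,
        params={"lam": lam, "goal_reward": goal_reward},
        metrics=_tidy(rows),
    )


# ---------------------------------------------------------------------------
# Stochastic transitions: two-step task and the failure case
# ---------------------------------------------------------------------------

def _two_step_stoch(rhat: np.ndarray, common_prob: float) -> StochasticTask:
    base = build_task(
        {"S1": ["SA", "SB"]},
        {"SA": float(rhat[0]), "SB": float(rhat[1])},
        nonterminal_rewards=0.0,
    )
    i1 = base.index("S1")
    S = np.array([[common_prob, 1.0 - common_prob], [1.0 - common_prob, common_prob]])
    models = {
        i1: ActionModel(
            actions=("A1", "A2"),
            successors=np.array([base.index("SA"), base.index("SB")]),
            S=S,
        )
    }
    return StochasticTask(base=base, models=models)


def run_two_step(
    n_trials: int = 10_000,
    reward: float = 0.25,
    persev: float = 0.75,
    seed: int = 0,
    common_prob: float = 0.7,
    learning_rate: float = 1.0,
    drift_sigma: float = 0.025,
    p_bounds=(0.25, 0.75),
    lam: float = 1.0,
) -> ExperimentResult:
    """Two-step Markov task: stay probabilities by reward × transition.

    First-stage actions reach their common second-stage state with
    probability ``common_prob``; terminal rewards are Bernoulli with
    independently drifting probabilities (reflected Gaussian walk).  Each
    trial the agent solves the task as if controllable, projects the
    desired marginal onto the two actions, and perseverates (repeats its
    previous choice) with probability ``persev``.  Model-based behavior
    shows as a reward × transition interaction in the stay probabilities.
    """
    if n_trials < 100:
        raise TaskError("insufficient trials: need at least 100")
    config = SolverConfig(lam=lam)
    rng = np.random.default_rng(seed)
    lo, hi = p_bounds
    p = rng.uniform(lo, hi, size=2)
    rhat = np.zeros(2)
    prev_choice = None
    prev_rewarded = None
    prev_common = None
    counts = {}  # (rewarded, common) -> [stays, total]

    for _ in range(n_trials):
        stoch = _two_step_stoch(rhat, common_prob)
        i1 = stoch.base.index("S1")
        u = marginal_dynamics(stoch, config)[i1]
        pi, _res = project_policy(stoch, u, i1, config)
        if prev_choice is not None and rng.random() < persev:
            choice = prev_choice
        else:
            choice = int(rng.random() < pi[1])  # 0=A1, 1=A2
        common = rng.random() < common_prob
        stage2 = choice if common else 1 - choice
        rewarded = rng.random() < p[stage2]
        r = reward if rewarded else 0.0
        rhat[stage2] += learning_rate * (r - rhat[stage2])

        if prev_choice is not None:
            key = (prev_rewarded, prev_common)
            c = counts.setdefault(key, [0, 0])
            c[0] += int(choice == prev_choice)
            c[1] += 1
        prev_choice, prev_rewarded, prev_common = choice, rewarded, common

        p = p + rng.normal(0.0, drift_sigma, size=2)
        p = np.where(p > hi, 2 * hi - p, p)
        p = np.where(p < lo, 2 * lo - p, p)
        p = np.clip(p, lo, hi)

    rows = []
    for (rewarded, common), (stays, total) in sorted(counts.items(), reverse=True):
        cond = ("rewarded" if rewarded else "unrewarded") + "_" + ("common" if common else "rare")
        rows.append((cond, "LRL", "stay_prob", stays / total if total else np.nan, 0))
        rows.append((cond, "LRL", "n", float(total), 0))
    return ExperimentResult(
        name="two_step",
        seed=seed,
        params={
            "n_trials": n_trials, "reward": reward, "persev": persev,
            "common_prob": common_prob, "learning_rate": learning_rate,
            "drift_sigma": drift_sigma, "p_bounds": tuple(p_bounds), "lam": lam,
        },
        metrics=_tidy(rows),
    )


def counterexample_task(spread: float = 10.0, s3_reward: float = 1.0) -> StochasticTask:
    """Stochastic task that defeats the controllability approximation.

    A1 leads surely to S2, whose actions both yield ±``spread`` at 50/50
    (exact value 0); A2 leads surely to S3 and a certain ``s3_reward``.
    Treating S2's outcome as controllable inflates its value.
    """
    base = build_task(
        {"S1": ["S2", "S3"], "S2": ["Tpos", "Tneg"], "S3": ["T3"]},
        {"Tpos": spread, "Tneg": -spread, "T3": s3_reward},
        nonterminal_rewards=0.0,
    )
    half = np.array([[0.5, 0.5], [0.5, 0.5]])
    models = {
        base.index("S1"): ActionModel(
            ("A1", "A2"), np.array([base.index("S2"), base.index("S3")]), np.eye(2)
        ),
        base.index("S2"): ActionModel(
            ("a", "b"), np.array([base.index("Tpos"), base.index("Tneg")]), half
        ),
        base.index("S3"): ActionModel(
            ("go",), np.array([base.index("T3")]), np.ones((1, 1))
        ),
    }
    return StochasticTask(base=base, models=models)


def run_counterexample(spread: float = 10.0, s3_reward: float = 1.0, lam: float = 1.0) -> ExperimentResult:
    """First-stage policy of the projection scheme vs the expectimax oracle."""
    config = SolverConfig(lam=lam)
    stoch = counterexample_task(spread, s3_reward)
    pp = stochastic_policy(stoch, config)
    i1 = stoch.base.index("S1")
    oracle = expectimax_oracle(stoch)
    rows = [
        ("counterexample", "LRL", "p_a1", float(pp.pi[i1][0]), 0),
        ("counterexample", "oracle", "greedy_action", float(oracle.greedy[i1]), 0),  # 0=A1, 1=A2
    ]
    return ExperimentResult(
        name="counterexample",
        seed=None,
        params={"spread": spread, "s3_reward": s3_reward, "lam": lam},
        metrics=_tidy(rows),
    )


# ---------------------------------------------------------------------------
# Habits: overtrained default policies
# ---------------------------------------------------------------------------

def run_habit_choice(
    episodes: int = 1000,
    alpha: float = 0.01,
    train_reward: float = 5.0,
    lams=(1.0, 3.0, 10.0),
    seed: int = 0,
) -> ExperimentResult:
    """Two-option task: overtraining the default toward B biases later
    choice of A (now rewarded), the more so the larger λ."""
    rng = np.random.default_rng(seed)
    # training-phase rewards: B rewarding, A worthless
    train = build_task({"C": ["A", "B"]}, {"A": 0.0, "B": train_reward}, nonterminal_rewards=0.0)
    ic, ia, ib = train.index("C"), train.index("A"), train.index("B")
    dp = DefaultPolicy.from_task(train, alpha)
    config1 = SolverConfig(lam=1.0)
    for _ in range(episodes):
        t = TaskGraph.from_matrix(train.state_ids, train.terminal_mask, dp.pi_d, train.r_A)
        sol = solve_values(t, None, config1)
        choice = ia if rng.random() < sol.policy[ic, ia] else ib
        delta_update(dp, ic, choice)
    rows = [("train", "LRL", "default_p_b", float(dp.pi_d[ic, ib]), 0)]
    test_r = {"A": train_reward, "B": 0.0}
    for lam in lams:
        cfg = SolverConfig(lam=lam)
        for agent, pi_d in (("trained", dp.pi_d), ("uniform", train.T)):
            t = TaskGraph.from_matrix(train.state_ids, train.terminal_mask, pi_d, train.r_A)
            t = t.with_terminal_rewards(test_r)
            sol = solve_values(t, None, cfg)
            rows.append((f"lam={lam:g}", agent, "p_a", float(sol.policy[ic, ia]), 0))
    return ExperimentResult(
        name="habit_choice",
        seed=seed,
        params={"episodes": episodes, "alpha": alpha, "train_reward": train_reward,
                "lams": tuple(lams)},
        metrics=_tidy(rows),
    )


def four_rooms_grid(terminal_cells: dict, cell_cost: float = -1.0) -> GridWorld:
    """An 11×11 grid split into four 5×5 rooms with one-cell doorways at
    (2,5), (8,5), (5,2) and (5,8)."""
    doors = {(2, 5), (8, 5), (5, 2), (5, 8)}
    blocked = {(5, c) for c in range(11)} | {(r, 5) for r in range(11)}
    blocked -= doors
    return build_gridworld(width=11, height=11, blocked=blocked, cell_cost=cell_cost,
                           terminal_cells=terminal_cells)


def _grid_task_with_default(
    reference: GridWorld, pi_d: np.ndarray, goal_cell, goal_reward: float, cell_cost: float = -1.0
) -> TaskGraph:
    """Rebuild the grid task with a given default and a relocated goal.

    Rows of states that were absorbing under the reference task (the old
    goal) fall back to the uniform default over open neighbors; the new
    goal's row becomes absorbing.
    """
    ref = reference.task
    n = ref.n_states
    T = pi_d.copy()
    terminal_mask = np.zeros(n, dtype=bool)
    r_A = np.full(n, cell_cost)
    gi = reference.state_of(goal_cell)
    # old absorbing rows -> uniform over geometric neighbors
    for i in range(n):
        if ref.terminal_mask[i]:
            nbrs = _open_neighbors(reference, i)
            T[i, :] = 0.0
            T[i, nbrs] = 1.0 / len(nbrs)
    T[gi, :] = 0.0
    T[gi, gi] = 1.0
    terminal_mask[gi] = True
    r_A[gi] = goal_reward
    return TaskGraph.from_matrix(ref.state_ids, terminal_mask, T, r_A)


def _open_neighbors(grid: GridWorld, i: int):
    r, c = grid.cell_of(i)
    out = []
    for cell in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
        try:
            out.append(grid.state_of(cell))
        except TaskError:
            continue
    return out


def run_habit_rooms(
    episodes: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    lam: float = 10.0,
    train_lam: float = 1.0,
    goal_reward: float = 5.0,
    start_cell=(8, 4),
    train_goal=(8, 8),
    same_room_goal=(7, 8),
    diff_room_goal=(2, 4),
    max_episode_steps: int = 2000,
) -> ExperimentResult:
    """Four-rooms navigation with an overtrained default policy.

    The default is delta-rule-trained while the agent navigates to
    ``train_goal`` (DR refreshed once per episode by the low-rank identity).
    During overtraining the agent acts at ``train_lam`` — a proficient,
    near-greedy policy, as after extensive practice — so the default
    concentrates on the habitual route; tests are evaluated at ``lam``,
    where the control cost weighs heavily and the habit expresses.  Tests
    move the goal within the trained room or to a different room and
    compare the trained default against a uniform one by expected steps to
    goal and by expected visits to the trained room.
    """
    config = SolverConfig(lam=lam)
    train_config = SolverConfig(lam=train_lam)
    rng = np.random.default_rng(seed)
    grid = four_rooms_grid({train_goal: goal_reward})
    task = grid.task
    start = grid.state_of(start_cell)
    dp = DefaultPolicy.from_task(task, alpha)
    dr = compute_dr(task, train_config)

    for _ in range(episodes):
        sol = solve_values(task, dr, train_config)
        policy = sol.policy
        cur = start
        changed = set()
        for _step in range(max_episode_steps):
            nxt = int(rng.choice(task.n_states, p=policy[cur]))
            delta_update(dp, cur, nxt)
            changed.add(cur)
            cur = nxt
            if task.terminal_mask[cur]:
                break
        task, dr = refresh_dr(dr, task, {i: dp.pi_d[i].copy() for i in changed}, train_config)

    old_room = [i for i in range(task.n_states)
                if grid.cell_of(i)[0] >= 6 and grid.cell_of(i)[1] >= 6]
    rows = [("train", "LRL", "episodes", float(episodes), 0)]
    for condition, goal_cell in (("same_room", same_room_goal), ("different_room", diff_room_goal)):
        for agent, pi_d in (("trained", dp.pi_d), ("uniform", None)):
            if pi_d is None:
                t = _grid_task_with_default(grid, four_rooms_grid({}).task.T, goal_cell, goal_reward)
            else:
                t = _grid_task_with_default(grid, pi_d, goal_cell, goal_reward)
            sol = solve_values(t, None, config)
            steps = expected_steps(t, sol.policy, start)
            visits = expected_visits(t, sol.policy, start)
            nt = t.nonterminal
            occ = float(sum(visits[np.searchsorted(nt, i)] for i in old_room if not t.terminal_mask[i]))
            rows.append((condition, agent, "expected_steps", steps, 0))
            rows.append((condition, agent, "old_room_visits", occ, 0))
    return ExperimentResult(
        name="habit_rooms",
        seed=seed,
        params={"episodes": episodes, "alpha": alpha, "lam": lam,
                "goal_reward": goal_reward, "start_cell": tuple(start_cell),
                "train_goal": tuple(train_goal), "same_room_goal": tuple(same_room_goal),
                "diff_room_goal": tuple(diff_room_goal)},
        metrics=_tidy(rows),
    )


# ---------------------------------------------------------------------------
# Cognitive control and Pavlovian-instrumental transfer
# ---------------------------------------------------------------------------

def _binary_choice_policy(default_correct: float, reward_correct: float, lam: float) -> float:
    """π(correct) in a one-step task with default weight ``default_correct``
    on the correct response and reward only for being correct."""
    task = build_task(
        {"C": ["correct", "wrong"]},
        {"correct": reward_correct, "wrong": 0.0},
        nonterminal_rewards=0.0,
        default_weights={"C": [default_correct, 1.0 - default_correct]},
    )
    sol = solve_values(task, None, SolverConfig(lam=lam))
    return float(sol.policy[task.index("C"), task.index("correct")])


def run_stroop(
    default_controlled: float = 0.2,
    reward_correct: float = 2.0,
    reward_boosts=(4.0, 8.0),
    lam: float = 1.0,
    seed: int = 0,
) -> ExperimentResult:
    """Error rates for automatic vs control-demanding responses.

    The control-demanding response (e.g. color naming) has a small default
    probability, so reliably producing it carries a large control cost and
    a larger error rate; raising the reward for correct responding reduces
    the effect.
    """
    rows = []
    for condition, p_default in (("automatic", 1.0 - default_controlled),
                                 ("controlled", default_controlled)):
        for r in (reward_correct, *reward_boosts):
            err = 1.0 - _binary_choice_policy(p_default, r, lam)
            rows.append((condition, "LRL", f"error_rate_r{r:g}", err, 0))
    return ExperimentResult(
        name="stroop",
        seed=seed,
        params={"default_controlled": default_controlled, "reward_correct": reward_correct,
                "reward_boosts": tuple(reward_boosts), "lam": lam},
        metrics=_tidy(rows),
    )


def run_pit(
    reward: float = 5.0,
    sated_reward: float = 0.0,
    trained_default: float = 0.5,
    lam: float = 1.0,
    seed: int = 0,
) -> ExperimentResult:
    """Outcome-specific Pavlovian-instrumental transfer.

    Pavlovian training raises the default probability of the cued outcome
    from 1/3 to ``trained_default`` (the two others split the remainder).
    With outcome rewards present the policy still favors the cued outcome;
    with all rewards zero the decision policy equals the default exactly,
    so the transfer persists under satiety.
    """
    other = (1.0 - trained_default) / 2.0
    rows = []
    for condition, r in (("rewarded", reward), ("sated", sated_reward)):
        task = build_task(
            {"choice": ["O1", "O2", "O3"]},
            {"O1": r, "O2": r, "O3": r},
            nonterminal_rewards=0.0,
            default_weights={"choice": [trained_default, other, other]},
        )
        sol = solve_values(task, None, SolverConfig(lam=lam))
        ic = task.index("choice")
        rows.append((condition, "LRL", "p_same", float(sol.policy[ic, task.index("O1")]), 0))
        rows.append((condition, "LRL", "p_different", float(sol.policy[ic, task.index("O2")]), 0))
    # no Pavlovian training: uniform default, uniform choice
    task = build_task({"choice": ["O1", "O2", "O3"]}, {"O1": reward, "O2": reward, "O3": reward},
                      nonterminal_rewards=0.0)
    sol = solve_values(task, None, SolverConfig(lam=lam))
    rows.append(("untrained", "LRL", "p_same",
                 float(sol.policy[task.index("choice"), task.index("O1")]), 0))
    return ExperimentResult(
        name="pit",
        seed=seed,
        params={"reward": reward, "sated_reward": sated_reward,
                "trained_default": trained_default, "lam": lam},
        metrics=_tidy(rows),
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

EXPERIMENTS = {
    "tree_benchmark": run_tree_benchmark,
    "shortest_path": run_shortest_path_suite,
    "latent_learning": run_latent_learning,
    "policy_revaluation": run_policy_revaluation,
    "detour": run_detour,
    "two_step": run_two_step,
    "counterexample": run_counterexample,
    "habit_choice": run_habit_choice,
    "habit_rooms": run_habit_rooms,
    "stroop": run_stroop,
    "pit": run_pit,
}


def run_experiment(name: str, **kwargs) -> ExperimentResult:
    """Dispatch an experiment by name (see :data:`EXPERIMENTS`)."""
    try:
        fn = EXPERIMENTS[name]
    except KeyError:
        valid = ", ".join(sorted(EXPERIMENTS))
        raise TaskError(f"unknown experiment {name!r}; valid names: {valid}") from None
    return fn(**kwargs)
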