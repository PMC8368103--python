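import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linrl import (
    SolverConfig,
    build_gridworld,
    build_task,
    compute_dr,
    decision_policy,
    policy_diagnostics,
    solve_values,
    value_iteration_oracle,
)
from conftest import make_random_dag_task


class TestComputeDR:
    def test_scalar_inverse(self, chain_task, config):
        dr = compute_dr(chain_task, config)
        np.testing.assert_allclose(dr.M, [[np.exp(-1.0)]], atol=1e-12)

    def test_nilpotent_chain(self):
        task = build_task({"a": ["b", "t"], "b": ["t"]}, {"t": 1.0}, 0.0)
        dr = compute_dr(task)
        # zero costs and a feed-forward chain: M = I + T_NN
        np.testing.assert_allclose(dr.M, np.eye(2) + task.T_NN, atol=1e-12)

    def test_matches_neumann_series(self, random_grid_factory, config):
        task = random_grid_factory(np.random.default_rng(7)).task
        dr = compute_dr(task, config)
        W = np.exp(task.r_N / config.lam)[:, None] * task.T_NN
        series = np.zeros_like(dr.M)
        term = np.diag(np.exp(task.r_N / config.lam))
        for _ in range(2000):
            series += term
            term = W @ term
        assert np.max(np.abs(dr.M - series)) < 1e-8

    def test_m_is_subblock_of_d_and_d_inverts_l(self, random_grid_factory, config):
        task = random_grid_factory(np.random.default_rng(9)).task
        dr = compute_dr(task, config)
        nt = task.nonterminal
        assert np.max(np.abs(dr.D[np.ix_(nt, nt)] - dr.M)) < 1e-10
        L = np.diag(np.exp(-task.r_A / config.lam)) - task.T
        assert np.max(np.abs(dr.D @ L - np.eye(task.n_states))) < 1e-8


class TestSolveValues:
    def test_forced_single_step(self, chain_task, config):
        sol = solve_values(chain_task, compute_dr(chain_task, config), config)
        assert abs(sol.v_star[0] - (-1.0)) < 1e-12

    def test_forced_two_step_chain(self, two_chain_task, config):
        sol = solve_values(two_chain_task, None, config)
        np.testing.assert_allclose(sol.v_star, [-2.0, -1.0], atol=1e-12)

    def test_forced_paths_exact_for_any_lambda(self):
        task = build_task({"a": ["b"], "b": ["c"], "c": ["t"]}, {"t": 2.0},
                          {"a": -1.0, "b": -3.0, "c": -2.0})
        oracle = value_iteration_oracle(task)
        for lam in (0.1, 1.0, 10.0, 1e4):
            sol = solve_values(task, None, SolverConfig(lam=lam))
            np.testing.assert_allclose(sol.v_star, oracle.v_bar, atol=1e-9)

    def test_iterative_and_direct_routes_agree(self):
        task = make_random_dag_task(np.random.default_rng(4))
        direct = solve_values(task, None, SolverConfig(lam=1.0))
        forced_iter = solve_values(task, None, SolverConfig(lam=1.0, overflow_guard=1e-9))
        np.testing.assert_allclose(direct.v_star, forced_iter.v_star, atol=1e-9)

    def test_shift_invariance_of_values_and_policy(self):
        task = make_random_dag_task(np.random.default_rng(11))
        sol = solve_values(task, None, SolverConfig())
        shifted = task.with_terminal_rewards(
            {task.state_ids[i]: task.r_A[i] + 100.0 for i in task.terminal})
        sol2 = solve_values(shifted, None, SolverConfig())
        np.testing.assert_allclose(sol2.v_star, sol.v_star + 100.0, atol=1e-8)
        np.testing.assert_allclose(sol2.policy, sol.policy, atol=1e-10)


class TestDecisionPolicy:
    def test_unit_reward_advantage_gives_073(self, two_option_task, config):
        sol = solve_values(two_option_task, None, config)
        p = sol.policy[two_option_task.index("C"), two_option_task.index("A")]
        assert abs(p - np.e / (1 + np.e)) < 1e-12
        assert round(float(p), 2) == 0.73

    def test_equal_values_reproduce_default_exactly(self):
        task = build_task({"C": ["A", "B", "D"]}, {"A": 2.0, "B": 2.0, "D": 2.0}, 0.0,
                          default_weights={"C": [0.5, 0.25, 0.25]})
        sol = solve_values(task, None, SolverConfig())
        row = sol.policy[task.index("C")]
        assert row[task.index("A")] == 0.5
        assert row[task.index("B")] == 0.25

    def test_infinite_cost_limit_recovers_default(self):
        task = make_random_dag_task(np.random.default_rng(2))
        sol = solve_values(task, None, SolverConfig(lam=1e6))
        nt = task.nonterminal
        assert np.max(np.abs(sol.policy[nt] - task.T[nt])) < 1e-4

    def test_softmax_equivalence_under_uniform_default(self, random_grid_factory):
        task = random_grid_factory(np.random.default_rng(21)).task
        cfg = SolverConfig()
        sol = solve_values(task, None, cfg)
        for i in task.nonterminal:
            succ = task.successors(int(i))
            x = sol.v_all[succ] / cfg.lam
            soft = np.exp(x - x.max())
            soft /= soft.sum()
            np.testing.assert_allclose(sol.policy[i, succ], soft, atol=1e-12)


class TestPolicyDiagnostics:
    def test_forced_state_has_zero_control_cost(self, two_chain_task, config):
        sol = solve_values(two_chain_task, None, config)
        diag = policy_diagnostics(two_chain_task, sol, config)
        np.testing.assert_allclose(diag.control_cost, 0.0, atol=1e-12)
        np.testing.assert_allclose(diag.gain, two_chain_task.r_N, atol=1e-12)

    def test_kl_matches_direct_arithmetic(self, two_option_task, config):
        sol = solve_values(two_option_task, None, config)
        diag = policy_diagnostics(two_option_task, sol, config)
        p = np.e / (1 + np.e)
        expected = p * np.log(p / 0.5) + (1 - p) * np.log((1 - p) / 0.5)
        i = list(two_option_task.nonterminal).index(two_option_task.index("C"))
        assert abs(diag.control_cost[i] - expected) < 1e-10
        assert abs(expected - 0.109) < 3e-3  # ~0.109 nats for the 0.73/0.27 split

    def test_unlikely_action_costs_more_than_likely_one(self):
        # same achieved policy asymmetry, mirrored defaults: the control
        # cost is higher when the reliable action is unlikely by default
        cfg = SolverConfig()
        costs = {}
        for name, weights in (("against", [0.2, 0.8]), ("with", [0.8, 0.2])):
            task = build_task({"C": ["A", "B"]}, {"A": 4.0, "B": 0.0}, 0.0,
                              default_weights={"C": weights})
            sol = solve_values(task, None, cfg)
            costs[name] = policy_diagnostics(task, sol, cfg).control_cost[0]
        assert costs["against"] > costs["with"]


class TestValueIterationOracle:
    def test_chain_distances(self):
        task = build_task({i: [i + 1] for i in range(5)}, {5: 0.0}, -1.0)
        oracle = value_iteration_oracle(task)
        np.testing.assert_allclose(oracle.v_bar, [-5, -4, -3, -2, -1], atol=1e-12)

    def test_maze_values_equal_bfs_distances(self):
        import networkx as nx
        from linrl.experiments import random_maze

        maze = random_maze(10, 10, 20, np.random.default_rng(5))
        goal = maze.cells[0]
        grid = build_gridworld(width=10, height=10, blocked=maze.blocked,
                               cell_cost=-1.0, terminal_cells={goal: 0.0})
        oracle = value_iteration_oracle(grid.task)
        g = nx.Graph()
        for i in range(grid.task.n_states):
            for j in grid.task.successors(i):
                if i != j:
                    g.add_edge(i, j)
        dist = nx.single_source_shortest_path_length(g, grid.state_of(goal))
        for k, i in enumerate(grid.task.nonterminal):
            assert oracle.v_bar[k] == -dist[int(i)]

    def test_tree_root_value_is_best_path_sum(self):
        from linrl.experiments import random_tree_task

        tree = random_tree_task(7, (0, 10), np.random.default_rng(8))
        oracle = value_iteration_oracle(tree.task)
        # exhaustive enumeration over all 128 root-leaf paths
        best = np.inf
        n_int = tree.n_internal
        for leaf in range(n_int, n_int + 2**7):
            cost, node = 0.0, leaf
            while True:
                cost += tree.costs[node]
                if node == 0:
                    break
                node = (node - 1) // 2
            best = min(best, cost)
        assert abs(oracle.v_bar[0] - (-best)) < 1e-9


class TestApproximationProperties:
    def test_error_nonincreasing_as_lambda_decreases(self):
        lams = (1.0, 0.3, 0.1, 0.03, 0.01)
        for seed in range(5):
            task = make_random_dag_task(np.random.default_rng(40 + seed), 8, 2)
            oracle = value_iteration_oracle(task)
            errs = [
                float(np.max(np.abs(
                    solve_values(task, None, SolverConfig(lam=lam)).v_star - oracle.v_bar)))
                for lam in lams
            ]
            assert all(errs[i] >= errs[i + 1] - 1e-9 for i in range(len(errs) - 1))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30)
    def test_policy_rows_are_distributions_on_default_support(self, seed):
        task = make_random_dag_task(np.random.default_rng(seed), 8, 2)
        cfg = SolverConfig(lam=float(np.random.default_rng(seed).uniform(0.2, 5.0)))
        sol = solve_values(task, None, cfg)
        nt = task.nonterminal
        np.testing.assert_allclose(sol.policy.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(sol.policy[nt][task.T[nt] == 0] == 0.0)
        # solution identity v* = r_N + lam * log c
        np.testing.assert_allclose(sol.v_star, task.r_N + cfg.lam * sol.log_c, atol=1e-8)
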