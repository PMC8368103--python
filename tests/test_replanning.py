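import numpy as np
import pytest

from linrl import (
    NumericalError,
    SolverConfig,
    add_goal,
    apply_transition_change,
    border_components,
    build_gridworld,
    build_task,
    compute_dr,
    dr_eigenmaps,
    greedy_path,
    learn_dr_incremental,
    plan_to_goal,
    solve_values,
)
from linrl.replanning import blocked_edge_rows
from conftest import make_random_grid


class TestAddGoal:
    def test_three_state_chain_matches_fresh_inversion(self, config):
        task = build_task({"a": ["b"], "b": ["t"]}, {"t": 2.0}, -1.0)
        dr = compute_dr(task, config)
        task2, dr2, upd = add_goal(dr, task, "b", goal_reward=3.0, config=config)
        fresh = compute_dr(task2, config)
        assert np.max(np.abs(dr2.D - fresh.D)) < 1e-10
        assert task2.terminal_mask[task2.index("b")]

    def test_update_vector_support_is_local(self, random_grid_factory, config):
        grid = random_grid_factory(np.random.default_rng(0))
        task = grid.task
        dr = compute_dr(task, config)
        j = int(task.nonterminal[0])
        _, _, upd = add_goal(dr, task, j, goal_reward=2.0, config=config)
        allowed = set(task.successors(j)) | {j}
        assert set(np.flatnonzero(upd.d)) <= allowed

    def test_zero_goal_reward_rejected(self, random_grid_factory, config):
        grid = random_grid_factory(np.random.default_rng(1))
        dr = compute_dr(grid.task, config)
        with pytest.raises(Exception, match="nonzero"):
            add_goal(dr, grid.task, int(grid.task.nonterminal[0]), goal_reward=0.0,
                     config=config)


class TestPlanToGoal:
    def test_z_matches_full_reinversion(self, random_grid_factory, config):
        grid = random_grid_factory(np.random.default_rng(2))
        task = grid.task
        dr = compute_dr(task, config)
        j = int(task.nonterminal[3])
        plan = plan_to_goal(dr, task, j, goal_reward=2.0, config=config)
        task2, dr2, _ = add_goal(dr, task, j, goal_reward=2.0, config=config)
        z_full = dr2.M @ task2.P
        scale = np.max(np.abs(z_full))
        assert np.max(np.abs(plan.z - z_full)) / scale < 1e-8

    def test_values_recoverable_from_z(self, random_grid_factory, config):
        grid = random_grid_factory(np.random.default_rng(12))
        task = grid.task
        dr = compute_dr(task, config)
        j = int(task.nonterminal[5])
        plan = plan_to_goal(dr, task, j, goal_reward=2.0, config=config)
        sol = solve_values(plan.task, None, config)
        nt = plan.task.nonterminal
        np.testing.assert_allclose(plan.v_all[nt], sol.v_star, atol=1e-8)


class TestTransitionChange:
    def test_identical_rows_are_a_null_update(self, random_grid_factory, config):
        grid = random_grid_factory(np.random.default_rng(4))
        task = grid.task
        dr = compute_dr(task, config)
        i = int(task.nonterminal[0])
        _, dr2, upd = apply_transition_change(dr, task, {i: task.T[i].copy()},
                                              config=config)
        assert np.max(np.abs(upd.B)) < 1e-12
        assert np.max(np.abs(dr2.D - dr.D)) < 1e-12

    def test_barrier_matches_fresh_inversion_and_rank_bound(self, config):
        for seed in range(12):
            rng = np.random.default_rng(200 + seed)
            grid = make_random_grid(rng, 6, 6, 5)
            task = grid.task
            dr = compute_dr(task, config)
            edges = _random_open_edges(grid, rng, n=2)
            if not edges:
                continue
            try:
                rows = blocked_edge_rows(grid, edges)
            except Exception:
                continue
            task2, dr2, upd = apply_transition_change(dr, task, rows, config=config)
            fresh = compute_dr(task2, config)
            scale = np.max(np.abs(fresh.D))
            assert np.max(np.abs(dr2.D - fresh.D)) / scale < 1e-8
            svals = np.linalg.svd(upd.B, compute_uv=False)
            assert np.sum(svals > 1e-10 * svals[0]) <= len(upd.J)


class TestGreedyPath:
    def test_adjacent_goal_single_step(self, config):
        grid = build_gridworld(width=3, height=3, blocked=[], cell_cost=-1.0,
                               terminal_cells={(0, 0): 5.0})
        sol = solve_values(grid.task, None, config)
        path = greedy_path(grid.task, sol, grid.state_of((0, 1)), grid.state_of((0, 0)))
        assert len(path) == 2

    def test_open_grid_corner_to_corner_is_manhattan(self, config):
        grid = build_gridworld(width=5, height=5, blocked=[], cell_cost=-1.0,
                               terminal_cells={(4, 4): 5.0})
        sol = solve_values(grid.task, None, config)
        path = greedy_path(grid.task, sol, grid.state_of((0, 0)), grid.state_of((4, 4)))
        assert len(path) - 1 == 8

    def test_unreachable_goal_raises(self, config):
        task = build_task({"a": ["b"], "b": ["a", "t"], "c": ["t"]}, {"t": 5.0}, -1.0)
        sol = solve_values(task, None, config)
        v = sol.v_all.copy()
        v[task.index("t")] = -100.0  # poisoned values make the walk cycle
        with pytest.raises(NumericalError, match="no convergent path"):
            greedy_path(task, v, "a", "t")


class TestIncrementalLearning:
    def test_empty_sequence_is_identity(self, random_grid_factory, config):
        grid = random_grid_factory(np.random.default_rng(6))
        dr = compute_dr(grid.task, config)
        task2, dr2 = learn_dr_incremental(dr, grid.task, [], config)
        assert np.array_equal(dr2.D, dr.D)

    def test_two_row_changes_compose_to_batch(self, config):
        rng = np.random.default_rng(31)
        grid = make_random_grid(rng, 6, 6, 5)
        task = grid.task
        dr = compute_dr(task, config)
        nts = [int(i) for i in task.nonterminal[:2]]
        rows = {}
        for i in nts:
            succ = task.successors(i)
            w = rng.dirichlet(np.ones(succ.size))
            row = np.zeros(task.n_states)
            row[succ] = w
            rows[i] = row
        _, dr_seq = learn_dr_incremental(dr, task, [(i, rows[i]) for i in nts], config)
        _, dr_batch, _ = apply_transition_change(dr, task, rows, config=config)
        scale = np.max(np.abs(dr_batch.D))
        assert np.max(np.abs(dr_seq.D - dr_batch.D)) / scale < 1e-8

    def test_grid_dr_built_row_by_row_from_absorbing_init(self, config):
        grid = build_gridworld(width=5, height=5, blocked=[], cell_cost=-1.0,
                               terminal_cells={(4, 4): 5.0})
        target = grid.task
        init = target.copy()
        init.T = np.eye(target.n_states)
        init.terminal_mask[:] = True
        dr0 = compute_dr(init, config)
        changes = [(int(i), target.T[i].copy()) for i in target.nonterminal]
        task_fin, dr_fin = learn_dr_incremental(dr0, init, changes, config)
        ref = compute_dr(target, config)
        assert np.max(np.abs(dr_fin.D - ref.D)) < 1e-6
        assert np.array_equal(task_fin.terminal_mask, target.terminal_mask)


@pytest.fixture(scope="module")
def walled_field():
    config = SolverConfig()
    grid = build_gridworld(width=20, height=20, blocked=[], cell_cost=-0.1,
                           terminal_cells={})
    dr = compute_dr(grid.task, config)
    rows = blocked_edge_rows(grid, [((10, 10), (10, 11))])
    _, _, barrier = apply_transition_change(dr, grid.task, rows, config=config)
    emap = dr_eigenmaps(dr, grid.task)
    return grid, dr, barrier, emap


class TestBorderComponents:
    def test_annihilated_eigenvector_gives_zero_column(self, walled_field):
        grid, dr, barrier, emap = walled_field
        u = emap.eigenvectors[:, 0]  # leading mode: barrier rows sum to zero
        b = border_components(dr, barrier, u[:, None])
        assert np.max(np.abs(b)) < 1e-10

    def test_components_localize_at_the_wall(self, walled_field):
        grid, dr, barrier, emap = walled_field
        wall = {(10, 10), (10, 11)}
        B_u = border_components(dr, barrier, emap.eigenvectors[:, :6])
        checked = 0
        for k in range(6):
            col = np.abs(B_u[:, k])
            if col.max() < 1e-10:
                continue
            r, c = grid.cell_of(int(np.argmax(col)))
            assert any(abs(r - wr) <= 1 and abs(c - wc) <= 1 for wr, wc in wall)
            checked += 1
        assert checked >= 3

    def test_full_basis_reconstructs_correction(self, walled_field):
        # B u = mu * b(u) for each eigenpair (mu, u) of the old D
        grid, dr, barrier, emap = walled_field
        V = emap.eigenvectors
        B_v = border_components(dr, barrier, V)
        recon = B_v * emap.eigenvalues[None, :]
        target = barrier.B @ V
        scale = max(np.max(np.abs(target)), 1e-12)
        assert np.max(np.abs(recon - target)) / scale < 1e-8


def _random_open_edges(grid, rng, n=2):
    task = grid.task
    pairs = []
    for i in task.nonterminal:
        for j in task.successors(int(i)):
            if j > i and not task.terminal_mask[j]:
                if task.successors(int(i)).size > 1 and task.successors(int(j)).size > 1:
                    pairs.append((grid.cell_of(int(i)), grid.cell_of(int(j))))
    if not pairs:
        return []
    idx = rng.choice(len(pairs), size=min(n, len(pairs)), replace=False)
    return [pairs[int(k)] for k in idx]
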