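# linrl — planning with a default representation

`linrl` is a Python library for solving sequential decision problems by
**linearly solvable control around a default policy**, a framework from
computational neuroscience for understanding how flexible planning,
grid/border-like spatial codes, habits, cognitive-control costs and
Pavlovian biases can all arise from one reuse strategy.  It is aimed at
computational cognitive scientists and RL researchers who want a compact,
well-tested reference implementation of the model and of the classic
behavioral simulations built on it.

## The model

Instead of the hard-max Bellman recursion, the agent optimizes a soft
objective that charges a control cost for deviating from a default policy
π<sup>d</sup>:

&nbsp;&nbsp;&nbsp;&nbsp;g(s) = r(s) − λ·KL(π ‖ π<sup>d</sup>)

With a one-to-one map between actions and successor states and a set of
absorbing goal ("terminal") states, the exponentiated optimal values are
**linear** in the exponentiated goal rewards:

&nbsp;&nbsp;&nbsp;&nbsp;exp(**v**\*/λ) = **M P** exp(**r**/λ),&nbsp;&nbsp;
**M** = (diag(exp(−**r**<sub>N</sub>/λ)) − **T**<sub>NN</sub>)<sup>−1</sup>

**M** — the *default representation* (DR) — is a goal-independent map of
cost-weighted long-run state expectancies under the default policy, so a
single cached DR replans under any change of goals.  The decision policy
is a weighted softmax, π(s′|s) ∝ π<sup>d</sup>(s′|s)·exp(v\*(s′)/λ).
Localized changes to the environment (new goals, barriers) update the DR
in place through the Woodbury identity at a cost of rank-|changed rows|,
and the correction columns in the DR's eigenbasis reproduce wall-locked,
border-cell-like response fields, while the eigenvectors themselves give
periodic, grid-like maps.

The package provides, in eight modules:

| module | contents |
| --- | --- |
| `task_model` | tasks, grid mazes, validation (spectral-radius / reachability) |
| `linear_solver` | the DR, closed-form values, weighted-softmax policy, KL diagnostics, exact value-iteration oracle |
| `replanning` | rank-1 goal addition, rank-|J| barrier updates, border components, greedy paths, incremental DR learning |
| `stochastic_control` | marginal-dynamics + simplex-projection extension, expectimax oracle |
| `default_learning` | delta-rule default-policy learning, low-rank DR refresh |
| `spectral_maps` | symmetrized eigen-decomposition of the DR |
| `experiments` | seeded reproductions of the behavioral simulation studies |
| `cli_io` | YAML/ASCII task formats, result serialization, the `linrl` CLI |

## Worked example

```python
from linrl import (SolverConfig, build_task, build_gridworld, compute_dr,
                   solve_values, plan_to_goal, greedy_path)

# A one-step choice: option A is worth 1 more than option B, uniform default.
task = build_task({"C": ["A", "B"]}, {"A": 1.0, "B": 0.0}, nonterminal_rewards=0.0)
sol = solve_values(task, None, SolverConfig(lam=1.0))
print("P(choose A) =", round(float(sol.policy[task.index("C"), task.index("A")]), 4))

# A maze with no goals: compute the DR once, then plan to any cell.
grid = build_gridworld(width=5, height=5, blocked=[(1, 1), (1, 2), (1, 3)],
                       cell_cost=-1.0, terminal_cells={})
dr = compute_dr(grid.task)
plan = plan_to_goal(dr, grid.task, grid.state_of((0, 2)), goal_reward=5.0)
path = greedy_path(plan.task, plan.v_all, grid.state_of((4, 2)), grid.state_of((0, 2)))
print("path:", [grid.cell_of(i) for i in path])
```

prints

```
P(choose A) = 0.7311
path: [(4, 2), (3, 2), (2, 2), (2, 1), (2, 0), (1, 0), (0, 0), (0, 1), (0, 2)]
```

The choice probability is the weighted softmax at unit reward advantage
(e/(1+e) ≈ 0.73): reward pulls toward A, the control cost pulls toward the
50/50 default.  The path is the greedy walk on values obtained from the
*goal-free* DR after a rank-1 update that makes (0,2) a goal — the wall at
row 1 forces the detour around the left side.  On a 10×10 maze with 20
blocked cells, greedy paths computed this way match breadth-first
shortest paths for **100%** of the 6 320 ordered state pairs:

```python
from linrl.experiments import run_shortest_path_suite
print(run_shortest_path_suite(seed=0).metrics)
#   fraction_optimal = 1.0,  n_pairs = 6320
```

The behavioral simulations are plain functions (and `linrl experiment`
subcommands): `run_tree_benchmark`, `run_latent_learning`,
`run_policy_revaluation`, `run_detour`, `run_two_step`,
`run_counterexample`, `run_habit_choice`, `run_habit_rooms`,
`run_stroop`, `run_pit`.  Each returns a tidy metrics table and is a pure
function of its parameters and seed.  See `docs/methods.md` for the model
details, numerical choices, and every reconstructed parameter.

## Command line

```bash
linrl solve --task task.yaml                  # optimal values per state
linrl plan --task task.yaml --start s --goal g --add-goal
linrl eig --task task.yaml --k 10 --out eig.csv
linrl experiment two_step --seed 7 --out out/
```

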