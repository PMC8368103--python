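# Methods

## Model

`linrl` solves finite decision tasks in which the agent controls a
probability distribution over successor states and pays, at every step, a
control cost for deviating from a default policy.  The per-state objective
is the gain

    g(s) = r(s) − λ·KL(π(·|s) ‖ π^d(·|s)),

with λ > 0 scaling the control cost in reward units per nat.  Two
structural assumptions make the problem linearly solvable: (i) there is a
one-to-one map between actions and successor states (fully controllable,
deterministic dynamics — a good fit for navigation), and (ii) the task has
absorbing terminal states carrying goal rewards `r`, while nonterminal
states carry traversal rewards `r_N` (usually negative costs).  Under
these assumptions the exponentiated optimal values satisfy a linear
equation,

    exp(v*/λ) = M P exp(r/λ),      M = (diag(exp(−r_N/λ)) − T_NN)^{-1},

where `T` is the row-stochastic default transition matrix, `T_NN` its
nonterminal block and `P` its nonterminal→terminal block.  `M` — the
default representation (DR) — is a cost-weighted map of long-run state
expectancies under the default policy.  It depends on the default policy
and the traversal costs but **not** on the goal rewards, which is what
makes it a reusable planning substrate: revaluing or moving goals only
changes `P exp(r/λ)`.  The decision policy is a weighted softmax,
`π(s'|s) ∝ π^d(s'|s)·exp(v*(s')/λ)`, with terminal successors entering at
their raw rewards (v at a terminal equals its reward).  As λ→0 the
solution approaches the exact (hard-max) optimum; as λ→∞ it collapses
onto the default policy.

A second inverse, `D = (diag(exp(−r_A/λ)) − T)^{-1}` over *all* states, is
kept for replanning; it exists only when every terminal reward is nonzero
(a zero reward makes that absorbing row of the system singular).  When a
task needs a zero terminal reward, `compute_dr` returns `M` only, which is
sufficient for all value computations; the low-rank update machinery
requires `D` and says so.

Tasks with *no* terminal states are legal whenever the cost-weighted
operator `diag(exp(r_N/λ))·T_NN` has spectral radius below one (strictly
negative traversal rewards suffice); this is the configuration used for
goal-free maps from which arbitrary goals are later added.  `validate_task`
reports this radius, reachability of terminals, and the largest exponent
`|r|/λ` the solver will encounter.

## Numerical choices

* **Shift-invariant exponentials.**  All softmax and linear-solve steps
  subtract the maximum exponent before exponentiating; values are
  recovered in log space.  Adding a constant to all terminal rewards
  shifts `v*` by that constant and leaves the policy unchanged (tested).
* **Log-space fixed point.**  When `max |r|/λ` exceeds
  `SolverConfig.overflow_guard` (default 500; float64 overflows near
  e^709), or when the accumulated path exponents underflow the direct
  product, `solve_values` switches to synchronous log-sum-exp sweeps of
  `v = r_N + λ·log Σ π^d exp(v'/λ)` (tolerance 1e-12, cap 1e5 sweeps).
  The fixed point is the same solution; the iteration is stable at
  arbitrarily small λ, which is how the λ→0 comparisons against exact
  value iteration are computed.
* **Oracle.**  The exact benchmark is synchronous value iteration on the
  hard-max Bellman recursion (tolerance 1e-12, cap 1e5 sweeps), greedy
  ties broken toward the lowest state index.  For stochastic tasks the
  oracle is expectimax value iteration (max over actions, expectation over
  outcomes).
* **Conditioning.**  `compute_dr` estimates the 1-norm condition number
  from the computed inverse and refuses (`DR not defined`) above 1e12.
* **Normalizer.**  The per-state normalizer `c` is kept as `log c`
  (a log-sum-exp over successors); the identity `v* = r_N + λ·log c` is
  asserted to 1e-8 in `policy_diagnostics`.

## Low-rank replanning

A localized change to the default dynamics alters a few rows of
`L = diag(exp(−r_A/λ)) − T`.  With `d` the row difference for a new goal
`j` (absorbing row, nonzero goal reward) and `m0 = D0[:, j]`,

    D = D0 − m0 (d D0) / (1 + d·m0),

and for a set `J` of changed rows with stacked differences `Δ`,

    D = D0 − B,   B = D0J (I + Δ D0J)^{-1} Δ D0,   rank(B) ≤ |J|.

Both updates reproduce a fresh inversion to ~1e-15 relative error on
random mazes (the test suite asserts <1e-8 over 50 randomized layouts).
Planning toward a new goal without committing the update uses
`ẑ = z0 − m0 (d z0)/(1+d·m0)` with `z0 = D0·P̂` (terminal rows zeroed);
the nonterminal rows of `ẑ` equal `M P` of the updated task.  Walls
block *both* directions of a grid edge, and each affected row
renormalizes the uniform default over the remaining open neighbors.
Updated representations are returned as new objects with a provenance
list; inputs are never mutated.  Applying single-row updates in sequence
equals the batch update, which is also how a DR can be grown row by row
from an all-absorbing initialization.

For the map-decomposition view, eigenvectors of `D0` pass through the
barrier correction as `b(u) = D0J (I + Δ D0J)^{-1} Δ u`; since the
trailing `D0` in `B` acts on its own eigenvector, `B·u = μ·b(u)`.  The
`b(u)` columns concentrate within one cell of the wall (border-field-like
maps), and a constant mode is annihilated because each barrier row
difference sums to zero.

## Spectral maps

For a uniform default on an undirected graph the nonterminal dynamics
satisfy detailed balance with the full-degree vector, so
`L_NN` is similar to a symmetric matrix via `diag(√deg)`.  `dr_eigenmaps`
detects this, solves the symmetric eigenproblem (guaranteeing a real
spectrum and an orthonormal conjugate-space basis, exposed as
`sym_vectors`), transforms back, unit-normalizes, and fixes signs (first
nonzero component positive).  Eigenvalues are reported for `M` itself
(`μ_M = 1/μ_L`), descending.  Non-reversible defaults fall back to a dense
nonsymmetric decomposition and raise if the spectrum is materially
complex.  Because `M` contains no goal information, eigenmaps are
bit-identical under changed terminal rewards.  On a ring the spectrum has
the closed form `1/(e^{c/λ} − cos(2πk/n))`, which the tests check exactly.

## Stochastic transitions

For tasks whose actions have stochastic outcomes, the solver first treats
the state dynamics as fully controllable and computes the desired marginal
transition distribution `u(·|s)` (the ordinary weighted-softmax policy of
the state-level task), then finds the action distribution minimizing
`‖S_s π − u‖²` on the simplex, where `S_s` is the successor×action model.
When the algebraic solution `S_s^{-1} u` is already a distribution it is
returned untouched; otherwise an SLSQP solve with simplex constraints is
used (ftol 1e-14) with an infinitesimal (1e-10) proximity term toward the
uniform action distribution to break exact ties deterministically.  The
approximation inherits a known failure mode: ignoring outcome
stochasticity at one state can distort the choice at its predecessors,
and the package ships the minimal task demonstrating it (a sure +1 branch
against a 50/50 ±10 branch whose exact value is 0); the projection prefers
the risky branch at every λ while expectimax does not, because the error
stems from the controllability assumption, not from softness.

## Default-policy learning

Observed transitions train the default by a normalized delta rule:
`π̂(s_b|s_a) ← π(s_b|s_a) + α(1−π(s_b|s_a))`, then the row is renormalized.
Rows remain exactly on the simplex and support never grows.  Note the
normalized rule approaches certainty *harmonically* (ε_{n+1} ≈ ε_n −
αε_n², so ε_n ~ 1/(αn)), not geometrically — relevant when reasoning
about overtraining durations.  Only visited rows are updated (no
off-trajectory decay).  The DR is refreshed from changed rows with the
same barrier identity; refreshing once per episode is the default cadence
in the habit experiments, and per-step refreshing (used in the
composition test) gives the same matrices to 1e-6.

## Simulation experiments and the synthetic study conditions

Every experiment is a pure function of its parameters and a seed; all the
linear-RL agents inside go through the single `solve_values`
implementation.  Experiment defaults are the study conditions of the
paradigms they emulate; quantities those conditions do not pin down were
chosen once, are exposed as function parameters, and are listed here.

* **Tree benchmark** — 100 random complete binary trees, seven levels of
  internal nodes (127 internal states, 128 leaves), i.i.d. U(0,10) costs
  at every state; agents minimize root-to-leaf cost.  Depth-D pruned
  searchers expand D levels exactly and substitute the exact uniform
  random-walk cost-to-go below the frontier (depth 1 is the on-policy
  successor representation of the random walk); the full-depth searcher
  is exactly optimal, and extra costs are computed against the optimal
  path summed in the same order (so its extra cost is exactly 0.0).
* **Shortest-path suite** — one 10×10 maze, 20 blocked cells sampled
  uniformly and resampled until the free region is connected, uniform
  cost 1, no terminals; one DR; every goal added by the rank-1 identity;
  greedy (mode-of-policy) paths compared against breadth-first lengths
  over all 6 320 ordered pairs.
* **Latent learning** — a 7×4 corridor maze with end boxes at ±ends;
  training rewards +5/+5 with cost 1 per step, devaluation sets the left
  box to −5.  Choice probabilities are exact absorption probabilities
  under the decision policy, and the test phase reuses the training `M`
  (only terminal rewards change).
* **Policy revaluation** — states 1,2,3 with zero rewards, terminals at
  (0, 5, 10); revaluation raises the worst terminal to 40.  These values
  are a reconstruction chosen so that the preference reversal holds for
  a uniform default *and* for the optimized training policy used as the
  default, while the successor representation under the training policy
  fails to reverse; with training terminals (0, 10, 20) the
  optimized-default reversal sits exactly on the decision boundary.
* **Detour** — a 5×3 maze with a straight 4-step corridor and an 8-step
  left loop; the wall removes the corridor's top edge (one default row
  changes, so the correction has rank 1) and the greedy path reroutes
  left using only the updated DR.
* **Two-step task** — 70/30 common/rare transitions, terminal reward
  0.25, perseveration as a 0.75 probability of repeating the previous
  first-stage choice (otherwise sampling the projected policy), 10⁴
  trials.  Reward probabilities follow independent reflected Gaussian
  walks (σ = 0.025) on [0.25, 0.75].  The agent's second-stage value
  estimate tracks the most recent outcome (delta rule with rate 1.0, the
  minimal-assumption estimator; slower tracking dilutes the
  reward×transition interaction below 2σ detectability at this trial
  count).  Stay probabilities are tabulated by the previous trial's
  reward and transition type.
* **Controllability counterexample** — S2's two actions both yield ±10 at
  50/50 (exact value 0); S3 leads surely to +1 (the continuation value is
  a reconstruction; only its sign relative to 0 matters).
* **Habit choice** — two options, training reward +5 on B, 1000 episodes
  of delta-rule training (α = 0.01) while acting under the current
  policy; at test the reward moves to A and the choice probability is
  evaluated at λ ∈ {1, 3, 10}.
* **Four-rooms habits** — an 11×11 grid, wall row/column 5 with doorways
  at (2,5), (8,5), (5,2), (5,8), giving four 5×5 rooms; cost 1, goal
  reward +5; start (8,4), training goal (8,8), 1000 episodes, α = 0.01.
  During overtraining the agent acts at λ = 1 (a proficient, near-greedy
  policy, as after extensive practice) so the default concentrates on the
  habitual corridor; tests are evaluated at λ = 10, where the control
  cost weighs heavily and the habit expresses.  The same-room test moves
  the goal to (7,8); the different-room test moves it to (2,4), whose
  short route opposes the habitual corridor while a long alternative runs
  through the trained room.  Performance is the exact expected number of
  steps to absorption under each decision policy, and the habit signature
  is the expected number of visits to the trained room.  In most other
  geometries the value function — which correctly prices future control
  costs — routes around the habit and the trained default never loses;
  the chosen layout is the reconstruction under which all three expected
  orderings hold.
* **Stroop** — one choice state; the control-demanding response has
  default probability 0.2 and correct responses earn +2; error rate is
  1 − π(correct), and reward boosts (+4, +8) are swept.
* **Pavlovian-instrumental transfer** — a choice over three outcomes with
  the cued outcome's default raised from 1/3 to 0.5 (others 0.25 each);
  outcome rewards +5, or 0 in the sated condition, where the policy
  equals the default exactly (P(same) = 0.50 by construction of the
  shifted softmax, which returns the default bit-exactly at equal
  values).

### What the synthetic conditions do and do not show

The generators emulate the *structure* of the behavioral paradigms —
graph topology, reward schedules, transition noise — not their biological
realizations: there is no response-time model, no trial-to-trial
motor/attention noise, no subject heterogeneity, and the default policies
are either exactly uniform or exactly delta-rule-trained.  Passing tests
therefore show that the algorithmic claims (exact replanning from a fixed
map, the signatures and biases, the failure cases) hold in their intended
regimes; they do not validate the model against empirical effect sizes
from behavioral or neural recordings.

## Problem sizes and runtime

The shipped test and acceptance runs use 10×10 mazes (shortest paths),
100×7-level trees, 50 randomized 6×6 mazes for the update-exactness
suite, 10⁴ two-step trials, and 1000 four-room training episodes on the
11×11 grid; the full suite completes in well under a minute on one CPU.
These sizes are the package's study conditions; all are parameters.

## Known limitations

* The linear solution requires the one-to-one action↔successor map;
  stochastic tasks are handled only through the marginal-projection
  approximation, with a documented counterexample.
* Objectives are total-reward-to-absorption; discounted or average-reward
  formulations are out of scope.
* The eigenmap symmetrization applies to reversible (uniform-default,
  undirected) dynamics; strongly non-reversible defaults may have complex
  spectra and are rejected rather than approximated.
* `D` (and hence Woodbury replanning) requires nonzero terminal rewards;
  greedy paths are invariant to the goal reward used, but the reward must
  not be exactly zero.
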