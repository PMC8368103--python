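"""Approximate control of stochastic-transition tasks.

The linear solver assumes fully controllable (deterministic) dynamics.
For tasks where actions have stochastic outcomes we follow a two-step
approximation: (1) solve the state-level task as if the agent could choose
its successor directly, yielding a desired marginal transition
distribution ``u(s'|s)``; (2) project that marginal onto the achievable
action policies, i.e. find π minimizing ``‖S_s π - u‖²`` on the simplex,
where ``S_s`` is the successor×action transition model at ``s``.

The exact benchmark for such tasks is expectimax value iteration (max over
actions, expectation over outcomes); the projection scheme can provably
disagree with it when ignoring outcome stochasticity at one state distorts
the optimal choice at its predecessors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .linear_solver import NumericalError, OracleSolution, solve_values
from .task_model import SolverConfig, TaskError, TaskGraph

__all__ = [
    "StochasticTask",
    "ProjectedPolicy",
    "marginal_dynamics",
    "project_policy",
    "stochastic_policy",
    "expectimax_oracle",
]

_FEASIBLE_TOL = 1e-10


@dataclass
class ActionModel:
    """Per-state transition model: rows successor states, columns actions."""

    actions: tuple
    successors: np.ndarray  # state indices, one per row of S
    S: np.ndarray  # successors x actions, each column a distribution

    def check(self) -> None:
        col = self.S.sum(axis=0)
        if np.any(self.S < 0) or np.any(np.abs(col - 1.0) > 1e-9):
            raise TaskError("each action column of S must be a distribution")


@dataclass
class StochasticTask:
    """A task graph plus per-state stochastic action models.

    ``base.T`` holds the *default state dynamics* π^d(s'|s); ``models``
    maps nonterminal state index → :class:`ActionModel` whose successor
    support must lie inside the base adjacency.
    """

    base: TaskGraph
    models: dict

    def check(self) -> None:
        for i, m in self.models.items():
            m.check()
            sup = set(np.flatnonzero(self.base.T[i] > 0))
            if not set(int(s) for s in m.successors) <= sup:
                raise TaskError(
                    f"successor support of state {self.base.state_ids[i]!r} "
                    "exceeds the base adjacency"
                )


@dataclass
class ProjectedPolicy:
    """Desired marginals, achievable action policy, and residuals."""

    u: np.ndarray  # full-state marginal transition matrix
    pi: dict  # state index -> action distribution
    residual: dict  # state index -> ||S_s pi - u||_2


def marginal_dynamics(stoch: StochasticTask, config: SolverConfig = SolverConfig()) -> np.ndarray:
    """Optimal marginal state transitions, treating the task as controllable.

    This is simply the weighted-softmax decision policy of the base task.
    """
    sol = solve_values(stoch.base, None, config)
    return sol.policy


def project_policy(stoch: StochasticTask, u: np.ndarray, state, config: SolverConfig = SolverConfig()):
    """Action distribution whose induced marginal best matches ``u(.|state)``.

    Solves ``S_s π = u`` directly when the algebraic solution is a
    distribution (returned untouched); otherwise minimizes the squared
    residual on the simplex, with ties broken toward the default policy by
    an infinitesimal proximity term.  Returns ``(pi, residual)``.
    """
    i = int(state) if isinstance(state, (int, np.integer)) else stoch.base.index(state)
    model = stoch.models[i]
    S = model.S
    target = np.asarray(u, dtype=float)
    if target.shape == (stoch.base.n_states,):
        target = target[model.successors]
    if target.shape != (S.shape[0],):
        raise TaskError("u must cover the state's successor set")
    if abs(target.sum() - 1.0) > 1e-9 or np.any(target < 0):
        raise TaskError("u must be a distribution over successors")

    k = S.shape[1]
    if S.shape[0] == k:
        try:
            pi = np.linalg.solve(S, target)
        except np.linalg.LinAlgError:
            pi = None
        if pi is not None and np.all(pi >= -_FEASIBLE_TOL) and abs(pi.sum() - 1.0) <= 1e-9:
            return pi, float(np.linalg.norm(S @ pi - target))

    # constrained least squares on the simplex (active-set style solver)
    pi_d = _default_actions(stoch, i)

    def objective(x):
        r = S @ x - target
        return 0.5 * float(r @ r) + 1e-10 * float((x - pi_d) @ (x - pi_d))

    def grad(x):
        return S.T @ (S @ x - target) + 2e-10 * (x - pi_d)

    res = minimize(
        objective,
        x0=pi_d,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0, "jac": lambda x: np.ones(k)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    pi = np.clip(res.x, 0.0, None)
    pi = pi / pi.sum()
    return pi, float(np.linalg.norm(S @ pi - target))


def _default_actions(stoch: StochasticTask, i: int) -> np.ndarray:
    k = stoch.models[i].S.shape[1]
    return np.full(k, 1.0 / k)


def stochastic_policy(stoch: StochasticTask, config: SolverConfig = SolverConfig()) -> ProjectedPolicy:
    """Full pipeline: marginal dynamics then per-state simplex projection."""
    stoch.check()
    u = marginal_dynamics(stoch, config)
    pi: dict = {}
    residual: dict = {}
    for i in stoch.models:
        p, r = project_policy(stoch, u[i], i, config)
        pi[i] = p
        residual[i] = r
    return ProjectedPolicy(u=u, pi=pi, residual=residual)


def expectimax_oracle(stoch: StochasticTask, tol: float = 1e-12, max_sweeps: int = 100_000) -> OracleSolution:
    """Exact values by expectimax value iteration: max over actions,
    expectation over the stochastic outcome of each action."""
    base = stoch.base
    nt = base.nonterminal
    v_all = np.where(base.terminal_mask, base.r_A, 0.0)
    r_N = base.r_N
    for _ in range(max_sweeps):
        v_new = np.empty(nt.size)
        for kk, i in enumerate(nt):
            m = stoch.models[int(i)]
            q = m.S.T @ v_all[m.successors]
            v_new[kk] = r_N[kk] + np.max(q)
        delta = np.max(np.abs(v_new - v_all[nt]), initial=0.0)
        v_all[nt] = v_new
        if delta < tol:
            break
    else:
        raise NumericalError("divergent values: no terminal reachable under any policy")
    greedy = np.full(base.n_states, -1, dtype=int)
    for i in nt:
        m = stoch.models[int(i)]
        q = m.S.T @ v_all[m.successors]
        greedy[i] = int(np.argmax(q))  # action index, lowest-index tie-break
    return OracleSolution(v_bar=v_all[nt].copy(), v_all=v_all, greedy=greedy)
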