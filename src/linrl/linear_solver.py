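"""Closed-form value solver for KL-regularized decision tasks.

Optimal control around a default policy with a control cost
``λ·KL(π‖π^d)`` makes the exponentiated value function linear in the
exponentiated goal rewards:

    exp(v*/λ) = M P exp(r/λ),        M = (diag(exp(-r_N/λ)) - T_NN)^{-1}

``M`` — the default representation (DR) — measures cost-weighted long-run
closeness of nonterminal states under the default policy and is independent
of the goal rewards, so one DR serves any assignment of goals.  The
decision policy is a weighted softmax of successor values, and the exact
(hard-max) Bellman solution is available as an oracle for comparison.

All exponentials are computed with the maximum exponent shifted out in log
space; when max |r|/λ exceeds the configured overflow guard (float64 caps
near e^709) the solver switches to synchronous log-sum-exp sweeps of the
softened Bellman recursion, which is exact at the fixed point and stable at
arbitrarily small λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .task_model import SolverConfig, TaskError, TaskGraph

__all__ = [
    "NumericalError",
    "DefaultRep",
    "ValueSolution",
    "PolicyDiagnostics",
    "OracleSolution",
    "compute_dr",
    "solve_values",
    "decision_policy",
    "policy_diagnostics",
    "value_iteration_oracle",
]


class NumericalError(RuntimeError):
    """The solver could not produce a well-defined numerical answer."""


# ---------------------------------------------------------------------------
# Default representation
# ---------------------------------------------------------------------------

@dataclass
class DefaultRep:
    """The default representation: M over nonterminal states, D over all.

    ``D = (diag(exp(-r_A/λ)) - T)^{-1}`` requires nonzero rewards at the
    absorbing terminal states; ``M`` is the nonterminal sub-block of ``D``.
    When some terminal reward is exactly zero, ``D`` is ``None`` and only
    ``M`` is available (replanning updates need ``D``).  ``provenance``
    records low-rank updates applied since the fresh inversion.
    """

    M: np.ndarray
    D: np.ndarray | None
    lam_used: float
    provenance: tuple = ()


def _l_matrix(task: TaskGraph, lam: float) -> np.ndarray:
    return np.diag(np.exp(-task.r_A / lam)) - task.T


def compute_dr(task: TaskGraph, config: SolverConfig = SolverConfig()) -> DefaultRep:
    """Invert the cost-weighted dynamics to obtain the DR (M and D).

    Raises
    ------
    NumericalError
        If the system is singular or ill-conditioned ("DR not defined"),
        e.g. when a zero-cost nonterminal cycle makes the series diverge, or
        a terminal state carries exactly zero reward.
    """
    lam = config.lam
    if np.max(np.abs(task.r_A)) / lam > config.overflow_guard:
        raise NumericalError(
            "DR not defined: max |r|/lambda exceeds the overflow guard; increase lambda"
        )
    nt = task.nonterminal
    if task.terminal.size == 0 or np.all(task.r_T != 0.0):
        L = _l_matrix(task, lam)
        try:
            D = np.linalg.inv(L)
        except np.linalg.LinAlgError as err:
            raise NumericalError(f"DR not defined: {err}") from err
        # one-norm condition estimate is cheap once the inverse is in hand
        cond1 = np.linalg.norm(L, 1) * np.linalg.norm(D, 1)
        if not np.isfinite(cond1) or cond1 > 1e12:
            raise NumericalError(f"DR not defined: condition number ~{cond1:.3g}")
        M = D[np.ix_(nt, nt)]
        return DefaultRep(M=M, D=D, lam_used=lam)
    # A zero terminal reward makes that absorbing row of L singular, so D
    # does not exist; M (all value computations need only M) still does.
    L_NN = np.diag(np.exp(-task.r_N / lam)) - task.T_NN
    try:
        M = np.linalg.inv(L_NN)
    except np.linalg.LinAlgError as err:
        raise NumericalError(f"DR not defined: {err}") from err
    cond1 = np.linalg.norm(L_NN, 1) * np.linalg.norm(M, 1)
    if not np.isfinite(cond1) or cond1 > 1e12:
        raise NumericalError(f"DR not defined: condition number ~{cond1:.3g}")
    return DefaultRep(M=M, D=None, lam_used=lam)


# ---------------------------------------------------------------------------
# Values and policy
# ---------------------------------------------------------------------------

@dataclass
class ValueSolution:
    """Optimal values, per-state normalizers, and the decision policy.

    ``v_star`` covers nonterminal states; ``v_all`` additionally holds the
    raw goal rewards at terminal states (terminal values equal their
    rewards).  ``log_c`` is the log normalizer of the weighted softmax; the
    identity ``v* = r_N + λ·log c`` holds at the solution.
    """

    v_star: np.ndarray
    v_all: np.ndarray
    log_c: np.ndarray
    policy: np.ndarray
    lam_used: float

    @property
    def expv(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.v_star / self.lam_used)

    @property
    def c(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.log_c)


@dataclass
class PolicyDiagnostics:
    """Per-state control cost KL(π‖π^d) in nats and gain g = r − λ·KL."""

    control_cost: np.ndarray
    gain: np.ndarray


def _log_t(task: TaskGraph) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(task.T > 0, np.log(np.maximum(task.T, 1e-300)), -np.inf)


def _iterative_values(task: TaskGraph, lam: float, tol: float = 1e-12, max_sweeps: int = 100_000) -> np.ndarray:
    """Synchronous log-sum-exp sweeps of v = r_N + λ·log Σ π^d exp(v'/λ)."""
    nt = task.nonterminal
    if nt.size == 0:
        return np.zeros(0)
    logT = _log_t(task)[nt]
    v_all = np.where(task.terminal_mask, task.r_A, 0.0)
    r_N = task.r_N
    for _ in range(max_sweeps):
        v_new = r_N + lam * logsumexp(logT + v_all[None, :] / lam, axis=1)
        delta = np.max(np.abs(v_new - v_all[nt]))
        v_all[nt] = v_new
        if delta < tol:
            return v_new
    raise NumericalError("value sweeps did not converge; no terminal reachable?")


def solve_values(
    task: TaskGraph,
    dr: DefaultRep | None = None,
    config: SolverConfig = SolverConfig(),
) -> ValueSolution:
    """Solve for optimal values and the weighted-softmax decision policy.

    With a cached ``dr`` the solution is the single matrix product
    ``exp(v*/λ) = M P exp(r/λ)`` (computed shift-invariantly in log space).
    Without one — or when max |r|/λ exceeds the overflow guard — a log-space
    fixed-point iteration is used instead.
    """
    lam = config.lam
    if dr is not None and abs(dr.lam_used - lam) > 1e-12:
        raise TaskError(f"DR built with lambda={dr.lam_used}, config has lambda={lam}")
    nt = task.nonterminal
    if task.terminal.size == 0:
        raise TaskError("no terminal states: values are undefined without goals")

    max_exp = float(np.max(np.abs(task.r_A))) / lam
    v_star = None
    if max_exp <= config.overflow_guard:
        m = float(np.max(task.r_T))
        y = np.exp((task.r_T - m) / lam)
        if dr is not None:
            w = dr.M @ (task.P @ y)
        else:
            L_NN = np.diag(np.exp(-task.r_N / lam)) - task.T_NN
            w = np.linalg.solve(L_NN, task.P @ y)
        if np.all(w > 0.0) and np.all(np.isfinite(w)):
            v_star = m + lam * np.log(w)
        # else: accumulated path exponents left the float64 range even
        # though single-step ones did not; fall through to log space
    if v_star is None:
        v_star = _iterative_values(task, lam)

    v_all = np.where(task.terminal_mask, task.r_A, 0.0)
    v_all[nt] = v_star
    logT = _log_t(task)[nt]
    log_c = logsumexp(logT + v_all[None, :] / lam, axis=1)
    sol = ValueSolution(v_star=v_star, v_all=v_all, log_c=log_c, policy=None, lam_used=lam)
    sol.policy = decision_policy(task, sol, config)
    return sol


def decision_policy(task: TaskGraph, values: ValueSolution, config: SolverConfig = SolverConfig()) -> np.ndarray:
    """Weighted softmax policy π(s'|s) ∝ π^d(s'|s)·exp(v*(s')/λ).

    Terminal successor values are their raw rewards; terminal rows stay
    absorbing; the policy has support only where the default does.
    """
    lam = config.lam
    if abs(values.lam_used - lam) > 1e-12:
        raise TaskError("values were solved under a different lambda")
    policy = np.zeros_like(task.T)
    for i in range(task.n_states):
        if task.terminal_mask[i]:
            policy[i, i] = 1.0
            continue
        sup = task.T[i] > 0
        if not np.any(sup):
            raise NumericalError(f"default support empty at state {task.state_ids[i]!r}")
        x = values.v_all[sup] / lam
        w = task.T[i, sup] * np.exp(x - np.max(x))  # shift keeps exp in range
        policy[i, sup] = w / w.sum()
    return policy


def policy_diagnostics(task: TaskGraph, values: ValueSolution, config: SolverConfig = SolverConfig()) -> PolicyDiagnostics:
    """Control cost KL(π‖π^d) and gain per nonterminal state.

    Also verifies the solution identity v* = r_N + λ·log c; a violation
    indicates an inconsistent (task, values) pair.
    """
    lam = config.lam
    nt = task.nonterminal
    resid = np.max(np.abs(values.v_star - (task.r_N + lam * values.log_c)), initial=0.0)
    if resid > 1e-8 * max(1.0, float(np.max(np.abs(values.v_star), initial=1.0))):
        raise NumericalError(f"value identity violated (residual {resid:.3g})")
    kl = np.zeros(nt.size)
    for k, i in enumerate(nt):
        pi = values.policy[i]
        sup = pi > 0
        kl[k] = float(np.sum(pi[sup] * (np.log(pi[sup]) - np.log(task.T[i, sup]))))
    gain = task.r_N - lam * kl
    return PolicyDiagnostics(control_cost=kl, gain=gain)


# ---------------------------------------------------------------------------
# Exact Bellman oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleSolution:
    """Exact optimal values v̄* and the greedy successor per state."""

    v_bar: np.ndarray
    v_all: np.ndarray
    greedy: np.ndarray


def value_iteration_oracle(task: TaskGraph, tol: float = 1e-12, max_sweeps: int = 100_000) -> OracleSolution:
    """Exact hard-max values by synchronous value iteration.

    Requires the deterministic action↔successor map: v̄(s) = r(s) +
    max_{s'∈succ(s)} v̄(s').  Greedy ties break toward the lowest state
    index.
    """
    nt = task.nonterminal
    n = task.n_states
    v_all = np.where(task.terminal_mask, task.r_A, 0.0)
    succs = [task.successors(int(i)) for i in nt]
    r_N = task.r_N
    for _ in range(max_sweeps):
        v_new = np.array([r_N[k] + np.max(v_all[s]) for k, s in enumerate(succs)])
        delta = np.max(np.abs(v_new - v_all[nt]), initial=0.0)
        v_all[nt] = v_new
        if delta < tol:
            break
    else:
        raise NumericalError("divergent values: no terminal reachable under any policy")
    greedy = np.full(n, -1, dtype=int)
    for k, i in enumerate(nt):
        s = succs[k]
        greedy[i] = int(s[np.argmax(v_all[s])])
    return OracleSolution(v_bar=v_all[nt].copy(), v_all=v_all, greedy=greedy)
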