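"""Low-rank, in-place updates of the default representation.

Making a state a new goal, inserting a barrier, or any other localized
change to the default dynamics alters only a few rows of the inverted
system ``L = diag(exp(-r_A/λ)) - T``.  The Woodbury matrix identity then
expresses the new inverse ``D`` in terms of the cached one, so replanning
costs a rank-|J| correction instead of a fresh n×n inversion:

    single row j changed:   D = D0 - m0 (d D0) / (1 + d m0)
    rows J changed:         D = D0 - D0J (I + Δ D0J)^{-1} Δ D0

The correction matrix ``B`` for a barrier has rank at most |J|, and its
columns in the eigenbasis of ``D0`` reproduce wall-adjacent response
fields (border components).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linear_solver import DefaultRep, NumericalError, ValueSolution
from .task_model import GridWorld, SolverConfig, TaskError, TaskGraph

__all__ = [
    "GoalUpdate",
    "BarrierUpdate",
    "GoalPlan",
    "add_goal",
    "plan_to_goal",
    "apply_transition_change",
    "border_components",
    "greedy_path",
    "learn_dr_incremental",
    "blocked_edge_rows",
]

_SINGULAR_TOL = 1e-12


@dataclass
class GoalUpdate:
    """Rank-1 correction that turns state ``j`` into an absorbing goal.

    ``d`` is the row difference of the cost-weighted dynamics (nonzero only
    at ``j`` and its successors), ``e`` the indicator column of ``j``,
    ``m0`` the j-th column of the old ``D``, and ``denom = 1 + d·m0``.
    """

    j: int
    d: np.ndarray
    e: np.ndarray
    m0: np.ndarray
    denom: float


@dataclass
class BarrierUpdate:
    """Rank-|J| correction for a set of changed transition rows.

    ``Delta`` stacks the row differences of ``L``; ``D0J`` holds the old
    ``D`` columns at ``J``; ``K = (I + Delta·D0J)^{-1}``; ``B = D0J·K·Delta·D0``
    satisfies ``D_new = D0 - B`` and has rank at most |J|.
    """

    J: tuple
    Delta: np.ndarray
    D0J: np.ndarray
    K: np.ndarray
    B: np.ndarray


@dataclass
class GoalPlan:
    """Result of planning toward a new goal without rebuilding the DR."""

    task: TaskGraph
    update: GoalUpdate
    z_hat: np.ndarray
    z: np.ndarray
    v_all: np.ndarray


def _require_d(dr: DefaultRep) -> np.ndarray:
    if dr.D is None:
        raise TaskError("this update needs the all-states DR D (zero terminal reward?)")
    return dr.D


def _l_row(task: TaskGraph, i: int, lam: float) -> np.ndarray:
    row = -task.T[i].copy()
    row[i] += np.exp(-task.r_A[i] / lam)
    return row


def _goal_task(task: TaskGraph, j: int, goal_reward: float) -> TaskGraph:
    new = task.copy()
    new.terminal_mask[j] = True
    new.T[j, :] = 0.0
    new.T[j, j] = 1.0
    new.r_A[j] = goal_reward
    return new


def _goal_update(dr: DefaultRep, task: TaskGraph, j: int, goal_reward: float, lam: float) -> tuple[TaskGraph, GoalUpdate]:
    if task.terminal_mask[j]:
        raise TaskError(f"state {task.state_ids[j]!r} is already terminal")
    if goal_reward == 0.0:
        raise TaskError("goal reward must be nonzero (zero makes D singular)")
    D0 = _require_d(dr)
    new_task = _goal_task(task, j, goal_reward)
    d = _l_row(new_task, j, lam) - _l_row(task, j, lam)
    e = np.zeros(task.n_states)
    e[j] = 1.0
    m0 = D0[:, j].copy()
    denom = 1.0 + float(d @ m0)
    if abs(denom) < _SINGULAR_TOL:
        raise NumericalError("singular update: 1 + d·m0 vanishes")
    return new_task, GoalUpdate(j=j, d=d, e=e, m0=m0, denom=denom)


def add_goal(
    dr: DefaultRep,
    task: TaskGraph,
    j,
    goal_reward: float = 1.0,
    config: SolverConfig = SolverConfig(),
) -> tuple[TaskGraph, DefaultRep, GoalUpdate]:
    """Make state ``j`` an absorbing goal and update the DR in place (rank 1).

    Returns the new task, a new :class:`DefaultRep` equal (to rounding) to a
    fresh inversion of the modified system, and the applied update.  A null
    update (``d = 0``) leaves ``D`` unchanged.
    """
    lam = config.lam
    ji = j if isinstance(j, (int, np.integer)) else task.index(j)
    new_task, upd = _goal_update(dr, task, int(ji), float(goal_reward), lam)
    D0 = dr.D
    D_new = D0 - np.outer(upd.m0, upd.d @ D0) / upd.denom
    nt = new_task.nonterminal
    dr_new = DefaultRep(
        M=D_new[np.ix_(nt, nt)],
        D=D_new,
        lam_used=lam,
        provenance=dr.provenance + (("goal", new_task.state_ids[int(ji)]),),
    )
    return new_task, dr_new, upd


def plan_to_goal(
    dr: DefaultRep,
    task: TaskGraph,
    j,
    goal_reward: float = 1.0,
    config: SolverConfig = SolverConfig(),
) -> GoalPlan:
    """Plan toward new goal ``j`` using the cached DR without updating it.

    Computes the plan vector ``ẑ = z0 - m0 (d z0)/(1 + d m0)`` with
    ``z0 = D0 P̂`` (terminal rows of the new task zeroed), whose nonterminal
    rows equal ``M P`` of the updated task.  Values follow from
    ``exp(v*/λ) = z exp(r_T/λ)``; the goal's own value is its reward.
    """
    lam = config.lam
    ji = int(j if isinstance(j, (int, np.integer)) else task.index(j))
    new_task, upd = _goal_update(dr, task, ji, float(goal_reward), lam)
    D0 = dr.D
    z0 = D0 @ new_task.P_hat
    z_hat = z0 - np.outer(upd.m0, upd.d @ z0) / upd.denom
    nt = new_task.nonterminal
    z = z_hat[nt]
    m = float(np.max(new_task.r_T))
    expv = z @ np.exp((new_task.r_T - m) / lam)
    if np.any(expv <= 0) or not np.all(np.isfinite(expv)):
        raise NumericalError("underflow; increase lambda")
    v_all = np.where(new_task.terminal_mask, new_task.r_A, 0.0)
    v_all[nt] = m + lam * np.log(expv)
    return GoalPlan(task=new_task, update=upd, z_hat=z_hat, z=z, v_all=v_all)


def apply_transition_change(
    dr: DefaultRep,
    task: TaskGraph,
    new_rows: dict,
    new_rewards: dict | None = None,
    config: SolverConfig = SolverConfig(),
) -> tuple[TaskGraph, DefaultRep, BarrierUpdate]:
    """Replace the default-transition rows of the states in ``new_rows``.

    ``new_rows`` maps state → full-length probability vector (its new
    default row); ``new_rewards`` optionally changes those states' rewards
    at the same time.  The DR is corrected with a rank-|J| Woodbury update;
    the result equals a fresh inversion of the modified system.
    """
    if not new_rows:
        raise TaskError("at least one changed row is required")
    lam = config.lam
    D0 = _require_d(dr)
    new_task = task.copy()
    J = []
    for state, row in new_rows.items():
        i = int(state) if isinstance(state, (int, np.integer)) else task.index(state)
        row = np.asarray(row, dtype=float)
        if row.shape != (task.n_states,) or np.any(row < 0) or abs(row.sum() - 1.0) > 1e-9:
            raise TaskError(f"invalid default: new row for state {state!r} is not a distribution")
        new_task.T[i] = row
        J.append(i)
    if new_rewards:
        for state, r in new_rewards.items():
            i = int(state) if isinstance(state, (int, np.integer)) else task.index(state)
            new_task.r_A[i] = float(r)
            if i not in J:
                J.append(i)
    J = sorted(J)
    Delta = np.stack([_l_row(new_task, i, lam) - _l_row(task, i, lam) for i in J])
    D0J = D0[:, J]
    core = np.eye(len(J)) + Delta @ D0J
    try:
        K = np.linalg.inv(core)
    except np.linalg.LinAlgError as err:
        raise NumericalError(f"inconsistent barrier: {err}") from err
    if np.linalg.cond(core) > 1e12:
        raise NumericalError("inconsistent barrier: correction system is singular")
    B = D0J @ (K @ (Delta @ D0))
    D_new = D0 - B
    nt = new_task.nonterminal
    upd = BarrierUpdate(J=tuple(new_task.state_ids[i] for i in J), Delta=Delta, D0J=D0J, K=K, B=B)
    dr_new = DefaultRep(
        M=D_new[np.ix_(nt, nt)],
        D=D_new,
        lam_used=lam,
        provenance=dr.provenance + (("rows", upd.J),),
    )
    return new_task, dr_new, upd


def border_components(dr: DefaultRep, barrier: BarrierUpdate, eigvecs: np.ndarray) -> np.ndarray:
    """Columns ``b(u) = D0J (I + Δ D0J)^{-1} Δ u`` for each eigenvector ``u``.

    ``eigvecs`` is an (n_states, k) stack of columns of the old ``D``'s
    eigenbasis.  Because the trailing ``D0`` of the correction ``B`` acts
    on its own eigenvector, ``B·u = μ·b(u)`` for eigenvalue μ, so stacking
    ``b`` over a full basis V reproduces ``B·V·diag(μ)^{-1}``.  The
    resulting maps concentrate near the changed transitions (walls).
    """
    U = np.atleast_2d(np.asarray(eigvecs, dtype=float))
    if U.shape[0] != barrier.D0J.shape[0]:
        raise TaskError("basis/DR mismatch: eigenvector length differs from state count")
    return barrier.D0J @ (barrier.K @ (barrier.Delta @ U))


def greedy_path(task: TaskGraph, values, start, goal, max_steps: int | None = None) -> list:
    """Follow the most probable successor under π from ``start`` to ``goal``.

    ``values`` may be a :class:`ValueSolution` or a full-state value vector.
    Ties break toward the lowest state index; a revisit before reaching the
    goal raises (``no convergent path``).  Returns state indices including
    both endpoints.
    """
    v_all = values.v_all if isinstance(values, ValueSolution) else np.asarray(values, dtype=float)
    si = int(start) if isinstance(start, (int, np.integer)) else task.index(start)
    gi = int(goal) if isinstance(goal, (int, np.integer)) else task.index(goal)
    if task.terminal_mask[si]:
        raise TaskError("start must be nonterminal")
    limit = max_steps if max_steps is not None else task.n_states
    path = [si]
    seen = {si}
    cur = si
    with np.errstate(divide="ignore"):
        logT = np.where(task.T > 0, np.log(np.maximum(task.T, 1e-300)), -np.inf)
    for _ in range(limit):
        row = logT[cur] + v_all
        nxt = int(np.argmax(row))
        if not np.isfinite(row[nxt]):
            raise NumericalError("no convergent path: empty successor set")
        path.append(nxt)
        if nxt == gi:
            return path
        if nxt in seen:
            raise NumericalError("no convergent path: cycle before reaching the goal")
        seen.add(nxt)
        cur = nxt
    raise NumericalError("no convergent path: step limit exceeded")


def learn_dr_incremental(
    dr: DefaultRep,
    task: TaskGraph,
    changes,
    config: SolverConfig = SolverConfig(),
) -> tuple[TaskGraph, DefaultRep]:
    """Apply a sequence of single-row changes by repeated rank-1 updates.

    ``changes`` is an iterable of ``(state, new_row)`` or
    ``(state, new_row, new_reward)``; applying them one by one reproduces a
    batch re-inversion, so the DR can be learned transition by transition
    (e.g. grown from an all-absorbing initialization).
    """
    lam = config.lam
    D = _require_d(dr).copy()
    cur = task.copy()
    prov = list(dr.provenance)
    for step, change in enumerate(changes):
        state, row = change[0], np.asarray(change[1], dtype=float)
        i = int(state) if isinstance(state, (int, np.integer)) else cur.index(state)
        new_task = cur.copy()
        new_task.T[i] = row
        new_task.terminal_mask[i] = bool(row[i] == 1.0 and np.sum(row) == row[i])
        if len(change) > 2:
            new_task.r_A[i] = float(change[2])
        d = _l_row(new_task, i, lam) - _l_row(cur, i, lam)
        m0 = D[:, i].copy()
        denom = 1.0 + float(d @ m0)
        if abs(denom) < _SINGULAR_TOL:
            raise NumericalError(f"singular update at step {step}")
        D -= np.outer(m0, d @ D) / denom
        prov.append(("row", new_task.state_ids[i]))
        cur = new_task
    nt = cur.nonterminal
    return cur, DefaultRep(M=D[np.ix_(nt, nt)], D=D, lam_used=lam, provenance=tuple(prov))


def blocked_edge_rows(grid: GridWorld, edges) -> dict:
    """New default rows after walling off grid edges (both directions).

    ``edges`` is an iterable of cell pairs; each pair loses its mutual
    transition and the uniform default renormalizes over the remaining open
    neighbors.  Returns a ``{state_index: row}`` dict for
    :func:`apply_transition_change`.
    """
    task = grid.task
    removed: dict[int, set[int]] = {}
    for a, b in edges:
        ia, ib = grid.state_of(a), grid.state_of(b)
        if task.T[ia, ib] == 0 and task.T[ib, ia] == 0:
            raise TaskError(f"cells {a} and {b} are not connected")
        removed.setdefault(ia, set()).add(ib)
        removed.setdefault(ib, set()).add(ia)
    rows = {}
    for i, gone in removed.items():
        if task.terminal_mask[i]:
            continue  # absorbing rows have no outgoing choice to renormalize
        keep = [j for j in task.successors(i) if j not in gone]
        if not keep:
            raise TaskError(
                f"blocking would strand cell {grid.cell_of(i)} with no open neighbor"
            )
        row = np.zeros(task.n_states)
        row[keep] = 1.0 / len(keep)
        rows[i] = row
    return rows
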