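"""Finite decision tasks with default dynamics.

The central object is :class:`TaskGraph`: a finite state space split into
nonterminal states (carrying traversal rewards, typically negative "costs")
and absorbing terminal states (carrying goal rewards), together with the
row-stochastic one-step transition matrix ``T`` induced by the default
policy.  Because actions are identified one-to-one with successor states,
a default policy *is* a transition matrix, and ``T[i, j]`` is the default
probability of stepping from state ``i`` to state ``j``.

Grid mazes (:class:`GridWorld`) are thin wrappers that map free cells to
states with a uniform default over open 4-neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import networkx as nx

__all__ = [
    "TaskError",
    "ValidationError",
    "SolverConfig",
    "TaskGraph",
    "TaskDiagnostics",
    "GridWorld",
    "build_task",
    "build_gridworld",
    "parse_grid_layout",
    "validate_task",
]

_ROW_TOL = 1e-12


class TaskError(ValueError):
    """A task description is malformed or inconsistent."""


class ValidationError(TaskError):
    """A structurally valid task fails a solvability requirement."""


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings.

    Parameters
    ----------
    lam:
        Control-cost scale λ > 0, in reward units per nat of KL divergence
        from the default policy.  λ → 0 recovers the exact (hard-max)
        optimum; λ → ∞ recovers the default policy.
    overflow_guard:
        Cap on max |r|/λ before the solver abandons the matrix-inverse route
        in favor of log-space iteration (float64 overflows near e^709).
    """

    lam: float = 1.0
    overflow_guard: float = 500.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise TaskError("lam must be positive")
        if not self.overflow_guard > 0:
            raise TaskError("overflow_guard must be positive")


@dataclass
class TaskGraph:
    """A finite task: states, terminal partition, default dynamics, rewards.

    Attributes
    ----------
    state_ids:
        Ordered state labels; matrices are indexed 0-based in this order.
    terminal_mask:
        Boolean per state; terminal states are absorbing in ``T``.
    T:
        Row-stochastic default transition matrix over all states.
    r_A:
        Reward per state (costs at nonterminal states, goal rewards at
        terminal states).
    """

    state_ids: tuple
    terminal_mask: np.ndarray
    T: np.ndarray
    r_A: np.ndarray

    @classmethod
    def from_matrix(cls, state_ids, terminal_mask, T, r_A, check: bool = True) -> "TaskGraph":
        task = cls(
            state_ids=tuple(state_ids),
            terminal_mask=np.asarray(terminal_mask, dtype=bool).copy(),
            T=np.asarray(T, dtype=float).copy(),
            r_A=np.asarray(r_A, dtype=float).copy(),
        )
        if check:
            task.check()
        return task

    def check(self) -> None:
        n = len(self.state_ids)
        if self.T.shape != (n, n):
            raise TaskError(f"T must be {n}x{n}, got {self.T.shape}")
        if self.terminal_mask.shape != (n,) or self.r_A.shape != (n,):
            raise TaskError("terminal_mask and r_A must have one entry per state")
        if np.any(self.T < -_ROW_TOL) or np.any(self.T > 1 + _ROW_TOL):
            raise TaskError("transition probabilities must lie in [0, 1]")
        rows = self.T.sum(axis=1)
        bad = np.flatnonzero(np.abs(rows - 1.0) > _ROW_TOL)
        if bad.size:
            raise TaskError(f"invalid default: row {bad[0]} sums to {rows[bad[0]]!r}")
        for i in np.flatnonzero(self.terminal_mask):
            if self.T[i, i] != 1.0:
                raise TaskError(f"terminal state {self.state_ids[i]!r} is not absorbing")

    # -- index helpers -----------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    @property
    def nonterminal(self) -> np.ndarray:
        return np.flatnonzero(~self.terminal_mask)

    @property
    def terminal(self) -> np.ndarray:
        return np.flatnonzero(self.terminal_mask)

    def index(self, state) -> int:
        try:
            return self.state_ids.index(state)
        except ValueError:
            raise TaskError(f"unknown state {state!r}") from None

    def successors(self, i: int) -> np.ndarray:
        """Indices of states reachable in one default step from state ``i``."""
        return np.flatnonzero(self.T[i] > 0)

    # -- matrix sub-blocks -------------------------------------------------
    @property
    def T_NN(self) -> np.ndarray:
        nt = self.nonterminal
        return self.T[np.ix_(nt, nt)]

    @property
    def P(self) -> np.ndarray:
        """Nonterminal → terminal block of ``T``."""
        return self.T[np.ix_(self.nonterminal, self.terminal)]

    @property
    def P_hat(self) -> np.ndarray:
        """All-states → terminal block of ``T`` with terminal rows zeroed."""
        ph = self.T[:, self.terminal].copy()
        ph[self.terminal, :] = 0.0
        return ph

    @property
    def r_N(self) -> np.ndarray:
        return self.r_A[self.nonterminal]

    @property
    def r_T(self) -> np.ndarray:
        return self.r_A[self.terminal]

    def copy(self) -> "TaskGraph":
        return TaskGraph(self.state_ids, self.terminal_mask.copy(), self.T.copy(), self.r_A.copy())

    def with_terminal_rewards(self, rewards: Mapping) -> "TaskGraph":
        """Return a copy with goal rewards changed (the DR is unaffected)."""
        out = self.copy()
        for state, r in rewards.items():
            i = self.index(state)
            if not self.terminal_mask[i]:
                raise TaskError(f"state {state!r} is not terminal")
            out.r_A[i] = float(r)
        return out


def build_task(
    adjacency: Mapping,
    terminal_rewards: Mapping,
    nonterminal_rewards=-1.0,
    default_weights: Mapping | None = None,
) -> TaskGraph:
    """Assemble a :class:`TaskGraph` from an adjacency description.

    Parameters
    ----------
    adjacency:
        Map from nonterminal state to the list of its successor states.
    terminal_rewards:
        Map from terminal state to its goal reward.  May be empty (goal-free
        tasks are legal whenever the cost-weighted dynamics contract).
    nonterminal_rewards:
        Scalar applied to every nonterminal state, or a map state → reward.
    default_weights:
        Optional map state → probability vector over that state's listed
        successors.  Omitted states get a uniform default.
    """
    if not adjacency and not terminal_rewards:
        raise TaskError("adjacency nonempty required")
    terminal_set = set(terminal_rewards)
    order: list = []
    seen = set()
    for s in adjacency:
        if s not in seen:
            order.append(s)
            seen.add(s)
    for s, succs in adjacency.items():
        for t in succs:
            if t not in seen:
                order.append(t)
                seen.add(t)
    for s in terminal_rewards:
        if s not in seen:
            order.append(s)
            seen.add(s)

    n = len(order)
    idx = {s: i for i, s in enumerate(order)}
    T = np.zeros((n, n))
    terminal_mask = np.zeros(n, dtype=bool)
    r_A = np.zeros(n)

    for s in order:
        i = idx[s]
        if s in terminal_set:
            terminal_mask[i] = True
            T[i, i] = 1.0
            r_A[i] = float(terminal_rewards[s])
            continue
        succs = list(adjacency.get(s, []))
        if not succs:
            raise TaskError(f"dead-end state: {s!r} has no successors and is not terminal")
        if default_weights is not None and s in default_weights:
            w = np.asarray(default_weights[s], dtype=float)
            if w.shape != (len(succs),) or np.any(w < 0) or abs(w.sum() - 1.0) > _ROW_TOL:
                raise TaskError(f"invalid default: weights for state {s!r} are not a distribution")
        else:
            w = np.full(len(succs), 1.0 / len(succs))
        for t, p in zip(succs, w):
            T[i, idx[t]] += p
        if isinstance(nonterminal_rewards, Mapping):
            r_A[i] = float(nonterminal_rewards[s])
        else:
            r_A[i] = float(nonterminal_rewards)

    return TaskGraph.from_matrix(order, terminal_mask, T, r_A)


# ---------------------------------------------------------------------------
# Grid worlds
# ---------------------------------------------------------------------------

@dataclass
class GridWorld:
    """A rectangular maze whose free cells form a :class:`TaskGraph`.

    Cells are 0-based ``(row, col)`` with a 4-neighborhood; walls remove
    edges in both directions and the uniform default renormalizes over the
    remaining open neighbors.
    """

    width: int
    height: int
    blocked: frozenset
    cell_cost: float
    terminal_cells: dict
    task: TaskGraph
    cells: tuple  # free cells in row-major order; cells[i] <-> state i
    dead_ends: tuple = ()

    def state_of(self, cell) -> int:
        return self.task.index(tuple(cell))

    def cell_of(self, i: int):
        return self.cells[i]

    def to_grid_array(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-state vector onto the (height, width) raster."""
        out = np.full((self.height, self.width), fill, dtype=float)
        for i, (r, c) in enumerate(self.cells):
            out[r, c] = values[i]
        return out


def parse_grid_layout(text: str):
    """Parse an ASCII maze: ``#`` wall, ``.`` free, letters A–Z terminal cells.

    Returns ``(height, width, blocked, letter_cells)`` where ``letter_cells``
    maps each letter to its cell.
    """
    rows = [line for line in text.splitlines() if line.strip()]
    if not rows:
        raise TaskError("empty grid layout")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise TaskError("layout rectangular required")
    blocked = set()
    letters = {}
    for r, line in enumerate(rows):
        for c, ch in enumerate(line):
            if ch == "#":
                blocked.add((r, c))
            elif ch == ".":
                pass
            elif ch.isalpha() and ch.isupper():
                if ch in letters:
                    raise TaskError(f"duplicate terminal letter {ch!r}")
                letters[ch] = (r, c)
            else:
                raise TaskError(f"unknown layout character {ch!r}")
    return len(rows), width, blocked, letters


def _neighbors(r, c, height, width):
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < height and 0 <= cc < width:
            yield rr, cc


def build_gridworld(
    layout=None,
    cell_cost: float = -1.0,
    terminal_cells: Mapping | None = None,
    *,
    width: int | None = None,
    height: int | None = None,
    blocked: Iterable | None = None,
    validate: bool = True,
) -> GridWorld:
    """Build a :class:`GridWorld` and its task graph.

    ``layout`` may be an ASCII maze (see :func:`parse_grid_layout`), in which
    case ``terminal_cells`` maps letters to rewards; alternatively pass
    ``width``/``height``/``blocked`` explicitly with ``terminal_cells``
    mapping ``(row, col)`` to rewards.

    With ``validate=True`` a free cell that cannot reach any terminal raises
    ``ValidationError("unreachable terminal ...")`` (skipped for goal-free
    mazes, whose solvability rests on the cost contraction instead).
    """
    terminal_cells = dict(terminal_cells or {})
    if isinstance(layout, str):
        height, width, blocked_set, letters = parse_grid_layout(layout)
        term = {}
        for letter, cell in letters.items():
            if letter not in terminal_cells:
                raise TaskError(f"no reward given for terminal letter {letter!r}")
            term[cell] = float(terminal_cells[letter])
        terminal_cells = term
    else:
        if width is None or height is None:
            raise TaskError("pass a layout string or explicit width/height")
        blocked_set = {tuple(b) for b in (blocked or ())}
        terminal_cells = {tuple(k): float(v) for k, v in terminal_cells.items()}

    if blocked_set & set(terminal_cells):
        raise TaskError("blocked and terminal cells must be disjoint")

    free = [
        (r, c)
        for r in range(height)
        for c in range(width)
        if (r, c) not in blocked_set
    ]
    if not free:
        raise TaskError("grid has no free cells")
    idx = {cell: i for i, cell in enumerate(free)}
    n = len(free)
    T = np.zeros((n, n))
    terminal_mask = np.zeros(n, dtype=bool)
    r_A = np.full(n, float(cell_cost))
    dead_ends = []

    for cell, i in idx.items():
        if cell in terminal_cells:
            terminal_mask[i] = True
            T[i, i] = 1.0
            r_A[i] = terminal_cells[cell]
            continue
        nbrs = [idx[nb] for nb in _neighbors(*cell, height, width) if nb in idx]
        if not nbrs:
            dead_ends.append(cell)
            T[i, i] = 1.0  # isolated cell: self-loop, flagged below
            continue
        T[i, nbrs] = 1.0 / len(nbrs)

    if validate and terminal_cells:
        g = nx.Graph()
        g.add_nodes_from(free)
        for cell in free:
            for nb in _neighbors(*cell, height, width):
                if nb in idx:
                    g.add_edge(cell, nb)
        reach = set()
        for t in terminal_cells:
            reach |= nx.node_connected_component(g, t)
        missing = [c for c in free if c not in reach]
        if missing:
            raise ValidationError(f"unreachable terminal: cell {missing[0]} is disconnected")
    if validate and dead_ends:
        raise ValidationError(f"unreachable terminal: isolated cell {dead_ends[0]}")

    task = TaskGraph.from_matrix(free, terminal_mask, T, r_A)
    return GridWorld(
        width=width,
        height=height,
        blocked=frozenset(blocked_set),
        cell_cost=float(cell_cost),
        terminal_cells=terminal_cells,
        task=task,
        cells=tuple(free),
        dead_ends=tuple(dead_ends),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class TaskDiagnostics:
    """Report from :func:`validate_task`."""

    ok: bool
    spectral_radius: float
    max_exponent: float
    unreachable: tuple
    warnings: tuple


def _spectral_radius(Q: np.ndarray) -> float:
    n = Q.shape[0]
    if n == 0:
        return 0.0
    if n <= 400:
        return float(np.max(np.abs(np.linalg.eigvals(Q))))
    try:
        from scipy.sparse.linalg import eigs

        val = eigs(Q, k=1, which="LM", return_eigenvectors=False, maxiter=5000)
        return float(np.abs(val[0]))
    except Exception:
        # power iteration fallback
        rng = np.random.default_rng(0)
        x = rng.standard_normal(n)
        x /= np.linalg.norm(x)
        rho = 0.0
        for _ in range(2000):
            y = Q @ x
            nrm = np.linalg.norm(y)
            if nrm == 0:
                return 0.0
            x = y / nrm
            rho = nrm
        return float(rho)


def validate_task(task: TaskGraph, config: SolverConfig = SolverConfig()) -> TaskDiagnostics:
    """Check that the default representation exists for this task.

    The DR series converges iff the spectral radius of
    ``diag(exp(r_N/λ)) @ T_NN`` is below one; we also report states that
    cannot reach any terminal and warn when |r|/λ risks exponential overflow.
    """
    warnings = []
    nt = task.nonterminal
    Q = np.exp(task.r_N / config.lam)[:, None] * task.T_NN
    rho = _spectral_radius(Q)
    max_exponent = float(np.max(np.abs(task.r_A)) / config.lam) if task.n_states else 0.0
    unreachable: list = []
    if task.terminal.size:
        g = nx.DiGraph()
        g.add_nodes_from(range(task.n_states))
        rows, cols = np.nonzero(task.T > 0)
        g.add_edges_from(zip(rows, cols))
        reach = set()
        rg = g.reverse()
        for t in task.terminal:
            reach |= set(nx.descendants(rg, int(t))) | {int(t)}
        unreachable = [task.state_ids[i] for i in nt if int(i) not in reach]
        if unreachable:
            warnings.append(f"{len(unreachable)} nonterminal state(s) cannot reach a terminal")
    if rho >= 1.0 - 1e-12:
        warnings.append("DR not defined: spectral radius >= 1")
    if max_exponent > config.overflow_guard:
        warnings.append(
            f"overflow risk: max |r|/lambda = {max_exponent:.3g} exceeds guard "
            f"{config.overflow_guard:.3g}; consider a larger lambda"
        )
    ok = rho < 1.0 - 1e-12 and not unreachable
    return TaskDiagnostics(
        ok=ok,
        spectral_radius=rho,
        max_exponent=max_exponent,
        unreachable=tuple(unreachable),
        warnings=tuple(warnings),
    )
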