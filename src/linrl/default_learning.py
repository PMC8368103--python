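"""Learning a non-uniform default policy from experienced transitions.

A delta rule nudges the default probability of each observed transition
toward 1 and renormalizes the row:

    π̂^d(s_b|s_a) ← π^d(s_b|s_a) + α (1 - π^d(s_b|s_a));   row ← π̂^d / Σ π̂^d

Repeated experience therefore concentrates the default on habitual
transitions, which later biases the decision policy toward them ("soft
habits").  The task's DR is refreshed from the changed rows with the same
low-rank inversion identity used for barriers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linear_solver import DefaultRep
from .replanning import apply_transition_change
from .task_model import SolverConfig, TaskError, TaskGraph

__all__ = ["DefaultPolicy", "delta_update", "refresh_dr"]


@dataclass
class DefaultPolicy:
    """A mutable row-stochastic default policy tied to a task's adjacency."""

    pi_d: np.ndarray
    alpha: float
    history: int = 0
    support: np.ndarray = None

    @classmethod
    def from_task(cls, task: TaskGraph, alpha: float = 0.01) -> "DefaultPolicy":
        if not 0.0 <= alpha <= 1.0:
            raise TaskError("invalid step-size: alpha must lie in (0, 1]")
        return cls(pi_d=task.T.copy(), alpha=float(alpha), support=(task.T > 0))

    def row(self, i: int) -> np.ndarray:
        return self.pi_d[i]


def delta_update(dp: DefaultPolicy, s_a: int, s_b: int) -> DefaultPolicy:
    """Apply one delta-rule update for the observed transition s_a → s_b.

    The update is in place and returns ``dp``; rows stay exactly on the
    simplex by construction of the normalization step, and support never
    grows beyond the original adjacency.
    """
    if not 0.0 <= dp.alpha <= 1.0:
        raise TaskError("invalid step-size: alpha must lie in (0, 1]")
    if dp.support is not None and not dp.support[s_a, s_b]:
        raise TaskError("observed transition is outside the adjacency")
    row = dp.pi_d[s_a]
    row[s_b] += dp.alpha * (1.0 - row[s_b])
    row /= row.sum()
    dp.history += 1
    return dp


def refresh_dr(
    dr: DefaultRep,
    task: TaskGraph,
    changed_rows,
    config: SolverConfig = SolverConfig(),
) -> tuple[TaskGraph, DefaultRep]:
    """Fold changed default rows into the cached DR (Woodbury, rank |J|).

    ``changed_rows`` maps state (index or id) → new row; an empty mapping
    returns the inputs unchanged.  Equivalent to a full re-inversion of the
    updated system.
    """
    if not changed_rows:
        return task, dr
    new_task, new_dr, _ = apply_transition_change(dr, task, dict(changed_rows), config=config)
    return new_task, new_dr
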