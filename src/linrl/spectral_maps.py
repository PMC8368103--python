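"""Eigen-decomposition of the default representation.

On undirected graphs with a uniform default, the cost-weighted dynamics
``L = diag(exp(-r_N/λ)) - T_NN`` are similar to a symmetric matrix via
degree scaling (``T_NN = D_deg^{-1} A`` with symmetric adjacency weights
``A``), so the DR has a real spectrum and its eigenvectors can be computed
in the symmetric conjugate space and transformed back.  Plotted over a 2-D
maze, low-order eigenvectors are periodic, grid-field-like maps; because
the DR is independent of the goal rewards, these maps are stable under
changes of goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linear_solver import DefaultRep, NumericalError
from .task_model import TaskError, TaskGraph

__all__ = ["EigenMap", "dr_eigenmaps"]


@dataclass
class EigenMap:
    """Top-k eigenpairs of the DR over nonterminal states.

    ``eigenvectors[:, i]`` is unit-norm with its first nonzero component
    positive; ``sym_vectors`` holds the orthonormal conjugate-space basis
    when symmetrization was used.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    symmetrization_used: bool
    sym_vectors: np.ndarray | None = None


def _fix_signs(V: np.ndarray) -> np.ndarray:
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    return V


def _symmetrizable(task: TaskGraph) -> np.ndarray | None:
    """Scaling vector d with d_i·T_ij = d_j·T_ji (detailed balance), if any.

    For a uniform default on an undirected graph the row probability is
    1/degree, so d is the (full) degree vector — including mass sent to
    absorbing terminal states, which leaves T_NN sub-stochastic but still
    similar to a symmetric matrix.
    """
    T = task.T_NN
    n = T.shape[0]
    d = np.zeros(n)
    for i in range(n):
        nz = T[i][T[i] > 0]
        if nz.size == 0 or np.ptp(nz) > 1e-12:
            return None
        d[i] = 1.0 / nz[0]
    A = d[:, None] * T
    if np.allclose(A, A.T, atol=1e-12):
        return d
    return None


def dr_eigenmaps(dr: DefaultRep, task: TaskGraph, k: int | None = None) -> EigenMap:
    """Top-k eigenpairs of M, ordered by descending eigenvalue.

    Uses the symmetric conjugate space whenever the default dynamics are a
    random walk on an undirected graph (guaranteeing a real spectrum and an
    orthogonal basis there); otherwise falls back to a dense nonsymmetric
    decomposition and raises if the spectrum is materially complex.
    """
    n = dr.M.shape[0]
    if k is None:
        k = n
    if not 1 <= k <= n:
        raise TaskError(f"k must lie in [1, {n}]")
    lam = dr.lam_used
    C = np.exp(-task.r_N / lam)
    L = np.diag(C) - task.T_NN

    deg = _symmetrizable(task)
    if deg is not None:
        s = np.sqrt(deg)
        H = (s[:, None] * L) / s[None, :]
        H = 0.5 * (H + H.T)  # kill rounding asymmetry
        mu, W = np.linalg.eigh(H)  # L eigenvalues ascending -> M descending
        vals = 1.0 / mu
        order = np.argsort(vals)[::-1]
        vals = vals[order]
        W = W[:, order]
        U = W / s[:, None]
        U /= np.linalg.norm(U, axis=0, keepdims=True)
        return EigenMap(
            eigenvalues=vals[:k].copy(),
            eigenvectors=_fix_signs(U[:, :k]),
            symmetrization_used=True,
            sym_vectors=_fix_signs(W[:, :k]),
        )

    vals, V = np.linalg.eig(dr.M)
    if np.max(np.abs(vals.imag)) > 1e-8 * np.max(np.abs(vals)):
        raise NumericalError("non-normal operator; use symmetrization")
    vals = vals.real
    V = V.real
    order = np.argsort(vals)[::-1]
    vals = vals[order][:k]
    V = V[:, order][:, :k]
    V /= np.linalg.norm(V, axis=0, keepdims=True)
    return EigenMap(
        eigenvalues=vals.copy(),
        eigenvectors=_fix_signs(V),
        symmetrization_used=False,
    )
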