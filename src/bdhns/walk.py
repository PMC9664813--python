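"""Random walk with restart over the heterogeneous network.

The walk iterates ``P(t+1) = (1 - r) W^T P(t) + r P(0)`` where W is the
row-stochastic transition matrix; the transpose puts the iteration in
column-stochastic orientation so each column of P stays a probability
distribution over nodes. With P(0) the identity, column j of P(t) is the
t-step diffusion profile seeded at node j — the neighbor-topology
feature vector consumed by the selection module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heteronet import TransitionMatrix


@dataclass(frozen=True)
class WalkProfile:
    """State of the restart walk after ``steps`` iterations."""

    P: np.ndarray
    restart: float
    steps: int
    converged: bool
    residual: float


def _transition_array(W) -> np.ndarray:
    if isinstance(W, TransitionMatrix):
        return W.values
    return np.asarray(W, dtype=float)


def enhanced_rwr(
    W,
    restart: float = 0.1,
    steps: int = 20,
    P0: np.ndarray | None = None,
    early_stop_tol: float | None = None,
) -> WalkProfile:
    """Run the restart walk for a fixed number of steps.

    Parameters
    ----------
    W : TransitionMatrix or array
        Row-stochastic transition matrix.
    restart : float in (0, 1]
        Probability of jumping back to the seed distribution each step.
    steps : int >= 0
        Number of iterations; the fixed step count is the primary
        stopping rule so runs are reproducible.
    P0 : array, optional
        Seed distributions, one column per seed; defaults to identity
        (each node seeds itself).
    early_stop_tol : float, optional
        If set, stop once the max-abs change between iterates falls
        below this tolerance.
    """
    if not 0 < restart <= 1:
        raise ValueError("restart probability must lie in (0, 1]")
    if steps < 0:
        raise ValueError("steps must be non-negative")
    Wt = _transition_array(W).T
    n = Wt.shape[0]
    P = np.eye(n) if P0 is None else np.asarray(P0, dtype=float).copy()
    if P.shape[0] != n:
        raise ValueError("P0 row count does not match the network size")
    seed = P.copy()
    residual = np.inf
    converged = False
    done = 0
    for _ in range(steps):
        nxt = (1.0 - restart) * (Wt @ P) + restart * seed
        residual = float(np.abs(nxt - P).max(initial=0.0))
        P = nxt
        done += 1
        if early_stop_tol is not None and residual < early_stop_tol:
            converged = True
            break
    if early_stop_tol is not None and residual < early_stop_tol:
        converged = True
    if steps == 0:
        residual = 0.0
    return WalkProfile(P, restart, done, converged, residual)


def rwr_closed_form(W, restart: float, P0: np.ndarray | None = None) -> np.ndarray:
    """Fixed point of the restart walk by direct linear solve.

    Solves ``(I - (1 - r) W^T) P = r P0``; the system is non-singular
    because the spectral radius of ``(1 - r) W^T`` is below 1 for a
    stochastic W and r in (0, 1). Used as the oracle for the iterative
    walk.
    """
    if not 0 < restart < 1:
        raise ValueError("restart probability must lie in (0, 1) for the fixed point")
    Wt = _transition_array(W).T
    n = Wt.shape[0]
    seed = np.eye(n) if P0 is None else np.asarray(P0, dtype=float)
    system = np.eye(n) - (1.0 - restart) * Wt
    if abs(np.linalg.det(system)) < np.finfo(float).tiny:
        raise np.linalg.LinAlgError("restart walk fixed-point system is singular")
    return np.linalg.solve(system, restart * seed)
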