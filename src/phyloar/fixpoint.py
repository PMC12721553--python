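"""Topological node embeddings by Dirichlet-energy minimization.

Each leaf ``x_i`` of a rank-``n`` tree is pinned to the one-hot vector
``delta_i`` in R^n; interior embeddings minimize the Dirichlet energy
``sum_{(u,v) in E} ||f(u) - f(v)||^2``.  The minimizer satisfies the harmonic
condition ``f(u) = mean of neighbors`` at every interior node (degree 3), i.e.
the linear system ``F = A F / 3 + C / 3`` with ``A`` the interior adjacency and
``C`` the leaf-interior cross adjacency.  Because the spectral radius of ``A``
is at most ``2 sqrt(2)`` for every tree shape, the Jacobi-style fixed-point
iteration ``F <- A F / 3 + C / 3`` contracts at rate ``2 sqrt(2) / 3 < 1``
uniformly over topologies, so the iteration count needed for a tolerance
``eps`` is a topology-independent constant.  The "power trick" reaches the
same iterate in logarithmically many squarings of the augmented matrix
``[[I, 0], [C/3, A/3]]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .treespace import OrdinalTreeState

__all__ = [
    "FixpointConfig",
    "CONTRACTION_RATE",
    "SPECTRAL_BOUND",
    "dirichlet_energy",
    "exact_embedding",
    "fixpoint_embedding",
    "interior_spectral_radius",
    "iteration_bound",
    "stack_adjacency",
    "pad_embeddings",
]

SPECTRAL_BOUND = 2.0 * np.sqrt(2.0)
CONTRACTION_RATE = SPECTRAL_BOUND / 3.0


@dataclass
class FixpointConfig:
    """Stopping tolerance and iteration mode for the fixed-point solver.

    ``epsilon`` bounds ``||F^(m) - F*||_F / n``; ``mode`` is ``"plain"``
    (one matrix product per step) or ``"power"`` (repeated squaring of the
    augmented matrix).  ``max_iters`` is a safety cap only.
    """

    epsilon: float = 1e-5
    mode: str = "plain"
    max_iters: int = 10_000

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.mode not in ("plain", "power"):
            raise ValueError(f"unknown mode {self.mode!r}")


def stack_adjacency(states: Sequence[OrdinalTreeState]) -> tuple[np.ndarray, np.ndarray]:
    """Stack equal-rank states into (B, n-2, n-2) and (B, n-2, n) float arrays."""
    ranks = {s.n for s in states}
    if len(ranks) != 1:
        raise ValueError("states in a batch must share the same rank")
    A = np.stack([s.A for s in states]).astype(float)
    C = np.stack([s.C for s in states]).astype(float)
    return A, C


def dirichlet_energy(F: np.ndarray, state: OrdinalTreeState) -> float:
    """Sum over edges of the squared distance between endpoint embeddings."""
    n = state.n
    F = np.asarray(F, dtype=float)
    if F.shape != (n - 2, n):
        raise ValueError(f"F must have shape {(n - 2, n)}, got {F.shape}")
    fbar = np.vstack([np.eye(n), F])
    rows = state.edge_rows()
    diffs = fbar[rows[:, 0]] - fbar[rows[:, 1]]
    return float((diffs ** 2).sum())


def exact_embedding(state: OrdinalTreeState) -> np.ndarray:
    """Direct solve of (I - A/3) F = C/3; the unique energy minimizer."""
    n = state.n
    A = state.A.astype(float)
    C = state.C.astype(float)
    return np.linalg.solve(np.eye(n - 2) - A / 3.0, C / 3.0)


def iteration_bound(epsilon: float, n: int) -> int:
    """Smallest m with c^m * sqrt(2 (n-2)) <= epsilon * n, c = 2 sqrt(2)/3.

    The a-priori initial error bound sqrt(2 (n-2)) uses one factor sqrt(2)
    per interior row (rows of both the constant-1/n start and the fixed
    point lie in the simplex, whose diameter is sqrt(2)).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if n < 3:
        raise ValueError("rank must be at least 3")
    e0 = np.sqrt(2.0 * (n - 2))
    target = epsilon * n
    if e0 <= target:
        return 1
    m = int(np.ceil(np.log(target / e0) / np.log(CONTRACTION_RATE)))
    return max(m, 1)


def fixpoint_embedding(
    states: Sequence[OrdinalTreeState] | OrdinalTreeState,
    config: FixpointConfig | None = None,
    n_iters: int | None = None,
) -> tuple[np.ndarray, int]:
    """Batched fixed-point solve of the embedding system.

    Parameters
    ----------
    states
        One state or a sequence of states of equal rank ``n``.
    config
        Tolerance and mode; defaults to plain iteration at ``eps = 1e-5``.
    n_iters
        Override the precomputed iteration count (used by diagnostics and
        the power-trick equivalence tests).

    Returns
    -------
    F : (B, n-2, n) interior embeddings (squeezed to 2-D for a single state)
    iters : number of plain-equivalent iterations performed
    """
    single = isinstance(states, OrdinalTreeState)
    batch = [states] if single else list(states)
    config = config or FixpointConfig()
    A, C = stack_adjacency(batch)
    n = batch[0].n
    m = n_iters if n_iters is not None else iteration_bound(config.epsilon, n)
    if m > config.max_iters:
        raise RuntimeError("iteration bound exceeds the safety cap; bug?")

    if config.mode == "power":
        k = int(np.ceil(np.log2(m))) if m > 1 else 0
        m_eff = 2 ** k
        B = A.shape[0]
        size = 2 * n - 2
        Abar = np.zeros((B, size, size))
        Abar[:, :n, :n] = np.eye(n)
        Abar[:, n:, :n] = C / 3.0
        Abar[:, n:, n:] = A / 3.0
        for _ in range(k):
            Abar = Abar @ Abar
        Fbar0 = np.concatenate(
            [np.broadcast_to(np.eye(n), (B, n, n)),
             np.full((B, n - 2, n), 1.0 / n)], axis=1)
        F = (Abar @ Fbar0)[:, n:, :]
        iters = m_eff
    else:
        F = np.full(A.shape[:2] + (n,), 1.0 / n)
        for _ in range(m):
            F = A @ F / 3.0 + C / 3.0
        iters = m

    return (F[0] if single else F), iters


def pad_embeddings(F: np.ndarray, n: int, N: int) -> np.ndarray:
    """Stack the identity leaf block on top and zero-pad to N columns.

    Input (B, n-2, n) -> output (B, 2n-2, N): rows 0..n-1 are the one-hot
    leaf embeddings, rows n..2n-3 the interior ones, columns n..N-1 zero.
    """
    F = np.asarray(F)
    squeeze = F.ndim == 2
    if squeeze:
        F = F[None]
    B = F.shape[0]
    out = np.zeros((B, 2 * n - 2, N))
    out[:, :n, :n] = np.eye(n)
    out[:, n:, :n] = F
    return out[0] if squeeze else out


def interior_spectral_radius(state: OrdinalTreeState) -> float:
    """Largest absolute eigenvalue of the interior adjacency matrix."""
    if state.n == 3:
        return 0.0
    vals = np.linalg.eigvalsh(state.A.astype(float))
    return float(np.abs(vals).max())
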