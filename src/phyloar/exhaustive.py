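"""Brute-force reference computations for small problem sizes.

These are deliberately naive, independent re-derivations used as oracles:
parsimony by enumerating all internal character assignments, likelihood by
summing over all internal-state extensions, model evidence by exhaustive
topology sums with quantile-grid branch integration, and the exact gradient
of a K-sample bound on an enumerable categorical toy model.  None of them
share code with the production paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from .alignment import Alignment
from .objectives import jc_transition, log_double_factorial, vimco_signals
from .treespace import Topology, enumerate_topologies

__all__ = [
    "brute_fitch",
    "brute_pruning_loglik",
    "evidence_bruteforce",
    "exact_multisample_bound_and_grad",
    "vimco_gradient_mc",
]


def brute_fitch(topology: Topology, alignment: Alignment) -> int:
    """Minimum change count by trying every internal assignment per site."""
    N = topology.N
    internals = sorted(k for k in topology.neighbors if k >= N)
    edges = topology.edges
    masks = alignment.state_masks()
    total = 0
    for site in range(alignment.n_sites):
        leaf_opts = [[b for b in range(4) if masks[i, site] >> b & 1]
                     for i in range(N)]
        best = None
        for assign in itertools.product(range(4), repeat=len(internals)):
            st = {k: a for k, a in zip(internals, assign)}
            for combo in itertools.product(*leaf_opts):
                st.update({i: c for i, c in enumerate(combo)})
                changes = sum(st[u] != st[v] for u, v in edges)
                best = changes if best is None else min(best, changes)
        total += best
    return total


def brute_pruning_loglik(topology: Topology, branch_lengths,
                         alignment: Alignment) -> float:
    """Likelihood as an explicit sum over all 4^(N-2) internal assignments."""
    N = topology.N
    internals = sorted(k for k in topology.neighbors if k >= N)
    edges = topology.edges
    q = np.asarray(branch_lengths, dtype=float)
    P = jc_transition(q)
    parts = alignment.partials()  # (N, M, 4)
    total = 0.0
    for site in range(alignment.n_sites):
        lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            st = dict(zip(internals, assign))
            for combo in itertools.product(
                    *[[b for b in range(4) if parts[i, site, b] > 0]
                      for i in range(N)]):
                st.update(dict(enumerate(combo)))
                term = 0.25  # stationary probability of the root state
                for e, (u, v) in enumerate(edges):
                    term *= P[e, st[u], st[v]]
                lik += term
        total += np.log(lik)
    return float(total)


def evidence_bruteforce(alignment: Alignment, grid: int = 8) -> float:
    """log p(Y) by exhaustive topology sum + quantile-grid branch integration.

    The Exp(10) prior integral per edge is approximated by averaging over
    ``grid`` midpoint quantiles; feasible only for N = 4 (5 edges).
    """
    from .objectives import pruning_loglik_batch

    N = len(alignment.taxa)
    if N != 4:
        raise ValueError("brute-force evidence is implemented for N = 4 only")
    u = (np.arange(grid) + 0.5) / grid
    qs = -np.log1p(-u) / 10.0  # Exp(10) quantiles
    topologies = enumerate_topologies(N, alignment.taxa)
    combos = np.array(list(itertools.product(qs, repeat=5)))  # (G^5, 5)
    per_topo = []
    for t in topologies:
        ll = pruning_loglik_batch(t, combos, alignment)
        mx = ll.max()
        per_topo.append(np.log(np.exp(ll - mx).mean()) + mx)
    per_topo = np.array(per_topo) - log_double_factorial(2 * N - 5)
    mx = per_topo.max()
    return float(np.log(np.exp(per_topo - mx).sum()) + mx)


# ---------------------------------------------------------------------------
# VIMCO on an enumerable categorical toy
# ---------------------------------------------------------------------------

def exact_multisample_bound_and_grad(logits: np.ndarray, f_values: np.ndarray,
                                     K: int) -> tuple[float, np.ndarray]:
    """Exact value and logit-gradient of the K-sample importance bound.

    The model is categorical over ``len(logits)`` states with unnormalized
    target values ``f_values``; the bound is
    ``E[log(1/K sum_i f(s_i) / q(s_i))]`` over i.i.d. K-tuples, enumerated
    exhaustively.  Gradients are found analytically via the score function
    of the tuple probability plus the pathwise term through ``q``.
    """
    logits = np.asarray(logits, dtype=float)
    S = len(logits)
    q = np.exp(logits - logits.max())
    q /= q.sum()
    logq = np.log(q)
    logf = np.log(np.asarray(f_values, dtype=float))
    value = 0.0
    grad = np.zeros(S)
    eye = np.eye(S)
    for tup in itertools.product(range(S), repeat=K):
        tup = np.array(tup)
        lw = logf[tup] - logq[tup]
        mx = lw.max()
        bound = np.log(np.exp(lw - mx).mean()) + mx
        p_tup = q[tup].prod()
        w = np.exp(lw - mx)
        wn = w / w.sum()  # normalized importance weights
        score = (eye[tup] - q).sum(axis=0)  # d log p(tuple) / d logits
        path = -(wn[:, None] * (eye[tup] - q)).sum(axis=0)  # through -log q
        value += p_tup * bound
        grad += p_tup * (bound * score + path)
    return float(value), grad


def vimco_gradient_mc(logits: np.ndarray, f_values: np.ndarray, K: int,
                      n_draws: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo VIMCO gradient estimates on the same categorical toy.

    Returns (mean gradient, standard error per coordinate) over ``n_draws``
    independent K-sample estimates, fully vectorized.
    """
    logits = np.asarray(logits, dtype=float)
    S = len(logits)
    q = np.exp(logits - logits.max())
    q /= q.sum()
    logq = np.log(q)
    logf = np.log(np.asarray(f_values, dtype=float))
    draws = rng.choice(S, size=(n_draws, K), p=q)
    lw = logf[draws] - logq[draws]  # (D, K)
    signals = vimco_signals(lw)
    mx = lw.max(axis=1, keepdims=True)
    w = np.exp(lw - mx)
    wn = w / w.sum(axis=1, keepdims=True)
    onehot = np.eye(S)[draws]  # (D, K, S)
    score = onehot - q
    per_draw = ((signals - wn)[:, :, None] * score).sum(axis=1)  # (D, S)
    mean = per_draw.mean(axis=0)
    sem = per_draw.std(axis=0, ddof=1) / np.sqrt(n_draws)
    return mean, sem
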