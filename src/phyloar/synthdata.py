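"""Synthetic study inputs: enumerable topology targets and JC alignments.

Stands in for posterior-style MCMC tree samples and benchmark alignments:
the toy target ``p(tau) proportional to exp(-lambda RF(tau, anchor))`` is
normalized by exhaustive enumeration, so KL divergences to it are exact, and
alignments are evolved forward under the Jukes-Cantor model, so the
generating process matches the likelihood used for inference.  Branch
lengths for simulation default to i.i.d. Exp(10) draws, matching the prior.
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment, BASES
from .objectives import jc_transition
from .treespace import (TaxaOrder, Topology, attach_leaf, enumerate_topologies,
                        init_state, rf_distance)

__all__ = [
    "ToyTarget",
    "random_topology",
    "toy_target",
    "sample_tree_set",
    "random_branch_lengths",
    "simulate_jc_alignment",
]


class ToyTarget:
    """An explicit distribution over all topologies of a small taxa set."""

    def __init__(self, topologies: list[Topology], probs: np.ndarray,
                 anchor: Topology | None = None, lam: float = 0.0):
        probs = np.asarray(probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("probabilities must be a distribution")
        self.topologies = topologies
        self.probs = probs
        self.anchor = anchor
        self.lam = lam
        self._index = {t: i for i, t in enumerate(topologies)}

    def prob_of(self, topology: Topology) -> float:
        return float(self.probs[self._index[topology]])

    def entropy(self) -> float:
        p = self.probs[self.probs > 0]
        return float(-(p * np.log(p)).sum())


def random_topology(N: int, seed) -> Topology:
    """Uniform draw over all (2N-5)!! topologies via uniform edge decisions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = init_state(TaxaOrder.generic(N))
    for n in range(3, N):
        state = attach_leaf(state, int(rng.integers(2 * n - 3)))
    return state.to_topology()


def toy_target(N: int, anchor: Topology | None = None, lam: float = 1.0,
               seed: int = 0) -> ToyTarget:
    """Gibbs distribution on RF distance to an anchor, exactly normalized."""
    if N > 7:
        raise ValueError("toy targets require exhaustive enumeration (N <= 7)")
    if anchor is None:
        anchor = random_topology(N, seed)
    topologies = enumerate_topologies(N, anchor.taxa)
    logits = np.array([-lam * rf_distance(t, anchor) for t in topologies])
    probs = np.exp(logits - logits.max())
    probs /= probs.sum()
    return ToyTarget(topologies, probs, anchor, lam)


def sample_tree_set(target: ToyTarget, size: int, seed
                    ) -> tuple[list[Topology], np.ndarray]:
    """I.i.d. draws from the target; returns unique trees + empirical weights."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(size, target.probs)
    keep = counts > 0
    trees = [t for t, k in zip(target.topologies, keep) if k]
    weights = counts[keep] / size
    return trees, weights


def random_branch_lengths(topology: Topology, seed,
                          rate: float = 10.0) -> np.ndarray:
    """I.i.d. Exp(rate) lengths aligned with ``topology.edges``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.exponential(1.0 / rate, size=len(topology.edges))


def simulate_jc_alignment(topology: Topology, branch_lengths, M: int,
                          seed) -> Alignment:
    """Evolve M i.i.d. sites down the tree under the Jukes-Cantor model.

    The root state is drawn from the uniform stationary distribution at the
    interior node next to the first leaf, and characters propagate edge by
    edge with the JC transition matrix.
    """
    if M < 1:
        raise ValueError("need at least one site")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = np.asarray(branch_lengths, dtype=float)
    edges = {e: i for i, e in enumerate(topology.edges)}
    P = jc_transition(q)  # (E, 4, 4)

    root = topology.neighbors[0][0]
    states = {root: rng.integers(4, size=M)}
    stack = [(v, root) for v in topology.neighbors[root]]
    while stack:
        node, parent = stack.pop()
        Pe = P[edges[(min(node, parent), max(node, parent))]]
        cum = Pe.cumsum(axis=1)
        u = rng.random(M)
        states[node] = (u[:, None] > cum[states[parent]]).sum(axis=1)
        for v in topology.neighbors[node]:
            if v != parent:
                stack.append((v, node))
    matrix = np.array([[BASES[s] for s in states[i]] for i in range(topology.N)])
    return Alignment(topology.taxa, matrix)
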