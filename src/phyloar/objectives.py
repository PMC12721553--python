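"""Training objectives: parsimony VI, density estimation, and VBPI.

Three ways to fit the autoregressive topology model:

* **Variational maximum parsimony** — the target is ``P(tau) proportional to
  exp(-S(tau; Y))`` with ``S`` the Fitch parsimony score; an annealed
  multi-sample lower bound is maximized with VIMCO gradients.
* **Tree-topology density estimation (TDE)** — maximum likelihood on a
  weighted collection of trees.
* **Variational Bayesian phylogenetic inference (VBPI)** — joint variational
  family ``Q_phi(tau) Q_psi(q | tau)`` against the annealed posterior under
  the Jukes-Cantor substitution model, a uniform topology prior and i.i.d.
  Exp(10) branch-length priors; topology gradients via VIMCO, branch-length
  gradients via the lognormal reparametrization trick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .alignment import Alignment
from .fixpoint import exact_embedding, pad_embeddings
from .model import ModelConfig, _mlp, _mlp_init, log_prob, sample
from .treespace import (OrdinalTreeState, Topology, attach_leaf, decompose,
                        init_state)

__all__ = [
    "fitch_score",
    "jc_transition",
    "pruning_loglik",
    "pruning_loglik_batch",
    "pruning_loglik_t",
    "log_double_factorial",
    "log_prior",
    "AnnealSchedule",
    "anneal_beta",
    "vimco_signals",
    "parsimony_elbo",
    "tde_loss",
    "kl_to_target",
    "init_branch_params",
    "branch_edge_features",
    "branch_loc_scale",
    "branch_sample_logpdf",
    "vbpi_bound",
    "marginal_likelihood_is",
]


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------

def _rooted_postorder(topology: Topology) -> list[tuple[int, list[int]]]:
    """Post-order (node, children) pairs rooting the tree at leaf 0."""
    order: list[tuple[int, list[int]]] = []
    stack = [(0, -1, False)]
    while stack:
        node, parent, done = stack.pop()
        kids = [v for v in topology.neighbors[node] if v != parent]
        if done:
            order.append((node, kids))
            continue
        stack.append((node, parent, True))
        for v in kids:
            stack.append((v, node, False))
    return order


def fitch_score(topology: Topology, alignment: Alignment) -> int:
    """Minimum number of character changes, summed over sites (Fitch).

    Each site is processed with state-set bitmasks on the tree rooted at
    leaf 0: an internal node's set is the intersection of its children's
    sets if non-empty, else their union, counting one change per union.
    The result does not depend on the rooting.
    """
    if topology.taxa != alignment.taxa:
        raise ValueError("topology and alignment taxa differ")
    masks = alignment.state_masks()  # (N, M)
    M = alignment.n_sites
    changes = np.zeros(M, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node, kids in _rooted_postorder(topology):
        if not kids:
            sets[node] = masks[node]
            continue
        acc = sets[kids[0]]
        for k in kids[1:]:
            inter = acc & sets[k]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | sets[k], inter)
        if node < topology.N:  # the root leaf itself: one final fold
            inter = acc & masks[node]
            changes += inter == 0
        sets[node] = acc
    return int(changes.sum())


# ---------------------------------------------------------------------------
# Jukes-Cantor likelihood
# ---------------------------------------------------------------------------

def jc_transition(q) -> np.ndarray:
    """JC69 transition matrix (or a batch of them for array input)."""
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("branch lengths must be non-negative")
    e = np.exp(-4.0 * q / 3.0)[..., None, None]
    eye = np.eye(4)
    return eye * (0.25 + 0.75 * e) + (1 - eye) * (0.25 - 0.25 * e)


def _branch_vector(topology: Topology, branch_lengths) -> np.ndarray:
    edges = topology.edges
    if isinstance(branch_lengths, dict):
        q = np.array([branch_lengths[e] for e in edges], dtype=float)
    else:
        q = np.asarray(branch_lengths, dtype=float)
    if q.shape[-1] != len(edges):
        raise ValueError(f"expected {len(edges)} branch lengths")
    return q


def pruning_loglik_batch(topology: Topology, branch_lengths,
                         alignment: Alignment) -> np.ndarray:
    """Felsenstein pruning under JC, batched over branch-length vectors.

    ``branch_lengths`` is (..., 2N-3) aligned with ``topology.edges``;
    returns the total log-likelihood with leading batch shape ``...``.
    """
    if topology.taxa != alignment.taxa:
        raise ValueError("topology and alignment taxa differ")
    q = _branch_vector(topology, branch_lengths)
    edges = {e: i for i, e in enumerate(topology.edges)}
    P = jc_transition(q)  # (..., E, 4, 4)
    leaf_partials = alignment.partials()  # (N, M, 4)
    batch = q.shape[:-1]
    M = alignment.n_sites

    partials: dict[int, np.ndarray] = {}
    scale_log = np.zeros(batch + (M,))
    root = topology.neighbors[0][0]  # interior node next to leaf 0
    order = [(n, [k for k in kids if k != 0])
             for n, kids in _rooted_postorder(topology) if n >= topology.N]
    # re-root at the interior node: leaf 0 becomes one of its children
    order[-1] = (root, order[-1][1] + [0])

    for node, kids in order:
        acc = np.ones(batch + (M, 4))
        for k in kids:
            Lk = partials[k] if k >= topology.N else \
                np.broadcast_to(leaf_partials[k], batch + (M, 4))
            e = edges[(min(node, k), max(node, k))]
            Pk = P[..., e, :, :]
            acc = acc * np.einsum("...mj,...ij->...mi", Lk, Pk)
        mx = np.maximum(acc.max(axis=-1, keepdims=True), 1e-300)
        acc = acc / mx
        scale_log += np.log(mx[..., 0])
        partials[node] = acc
    site_lik = 0.25 * partials[root].sum(axis=-1)
    return (np.log(site_lik) + scale_log).sum(axis=-1)


def pruning_loglik(topology: Topology, branch_lengths,
                   alignment: Alignment) -> float:
    return float(pruning_loglik_batch(topology, branch_lengths, alignment))


def pruning_loglik_t(topology: Topology, q: Tensor,
                     alignment: Alignment) -> Tensor:
    """Differentiable pruning log-likelihood w.r.t. the branch lengths ``q``."""
    edges = {e: i for i, e in enumerate(topology.edges)}
    leaf_partials = alignment.partials()
    M = alignment.n_sites
    eye = np.eye(4)
    root = topology.neighbors[0][0]
    order = [(n, [k for k in kids if k != 0])
             for n, kids in _rooted_postorder(topology) if n >= topology.N]
    order[-1] = (root, order[-1][1] + [0])

    partials: dict[int, Tensor] = {}
    for node, kids in order:
        acc = ad.constant(np.ones((M, 4)))
        for k in kids:
            Lk = partials[k] if k >= topology.N else ad.constant(leaf_partials[k])
            e = edges[(min(node, k), max(node, k))]
            decay = (q[e] * (-4.0 / 3.0)).exp().reshape(1, 1)
            Pk = ad.constant(eye) * (0.25 + 0.75 * decay) \
                + ad.constant(1 - eye) * (0.25 - 0.25 * decay)
            acc = acc * (Lk @ Pk.swapaxes(-1, -2))
        partials[node] = acc
    site = (partials[root] * 0.25).sum(axis=-1)
    return site.log().sum()


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def log_double_factorial(k: int) -> float:
    """log k!! for odd k (number of unrooted topologies is (2N-5)!!)."""
    return float(np.log(np.arange(k, 0, -2)).sum())


def log_prior(topology: Topology, branch_lengths) -> float:
    """Uniform topology prior + i.i.d. Exp(10) branch-length prior."""
    q = _branch_vector(topology, branch_lengths)
    if (q < 0).any():
        raise ValueError("branch lengths must be non-negative")
    N = topology.N
    return float(-log_double_factorial(2 * N - 5)
                 + (np.log(10.0) - 10.0 * q).sum())


# ---------------------------------------------------------------------------
# Annealing and VIMCO
# ---------------------------------------------------------------------------

@dataclass
class AnnealSchedule:
    """beta_t = min(1, floor + t / period), non-decreasing to 1."""

    period: int
    floor: float = 0.001

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")


def anneal_beta(t: int, schedule: AnnealSchedule) -> float:
    if t < 0:
        raise ValueError("t must be non-negative")
    return min(1.0, schedule.floor + t / schedule.period)


def vimco_signals(log_weights: np.ndarray) -> np.ndarray:
    """Leave-one-out learning signals for a multi-sample bound.

    ``signal_i = L_hat - L_hat_{-i}`` where ``L_hat`` is the log-mean-exp of
    the K log-weights and ``L_hat_{-i}`` replaces weight i by the geometric
    mean of the others (arithmetic mean of their log-weights).
    """
    l = np.asarray(log_weights, dtype=float)
    K = l.shape[-1]
    if K < 2:
        raise ValueError("VIMCO needs at least 2 samples")
    total = l.sum(axis=-1, keepdims=True)
    loo_mean = (total - l) / (K - 1)  # mean of the other log-weights
    mx = l.max(axis=-1, keepdims=True)
    full = np.log(np.exp(l - mx).sum(axis=-1, keepdims=True)) + mx - np.log(K)
    # replace l_i by loo_mean_i, one i at a time, vectorized
    e = np.exp(l - mx)
    sum_others = e.sum(axis=-1, keepdims=True) - e
    repl = np.log(sum_others + np.exp(loo_mean - mx)) + mx - np.log(K)
    return np.squeeze(full, -1)[..., None] - repl


def _log_mean_exp(l: Tensor) -> Tensor:
    K = l.shape[-1]
    return ad.logsumexp(l, axis=-1) - np.log(K)


def parsimony_elbo(params: dict, config: ModelConfig, alignment: Alignment,
                   K: int, beta: float, rng) -> dict:
    """One K-sample annealed parsimony bound with its VIMCO surrogate loss.

    Returns a dict with the bound value, per-sample log-weights, sampled
    topologies, their parsimony scores, and a ``surrogate`` tensor whose
    gradient is the VIMCO estimator of the (negated) bound gradient.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    trees, logq = sample(params, config, alignment.taxa, K, rng)
    scores = np.array([fitch_score(t, alignment) for t in trees], dtype=float)
    l = ad.constant(-beta * scores) - logq
    bound = _log_mean_exp(l)
    if K >= 2:
        signals = vimco_signals(l.data)
        surrogate = -(bound + (ad.constant(signals) * logq).sum())
    else:
        surrogate = -(bound + (ad.constant(l.data) * logq).sum())
    return {
        "bound": bound.item(),
        "log_weights": l.data.copy(),
        "scores": scores,
        "topologies": trees,
        "surrogate": surrogate,
    }


# ---------------------------------------------------------------------------
# Density estimation
# ---------------------------------------------------------------------------

def tde_loss(params: dict, config: ModelConfig, trees: Sequence[Topology],
             weights, batch_size: int | None, rng) -> Tensor:
    """Negative weighted log-likelihood on a weight-sampled minibatch."""
    if len(trees) == 0:
        raise ValueError("empty training set")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    if batch_size is None:
        logp = log_prob(params, config, list(trees))
        return -(ad.constant(w) * logp).sum()
    idx = rng.choice(len(trees), size=batch_size, p=w)
    logp = log_prob(params, config, [trees[i] for i in idx])
    return -logp.mean()


def kl_to_target(params: dict, config: ModelConfig,
                 trees: Sequence[Topology], weights) -> float:
    """KL(target || model) over an explicit weighted topology set."""
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("target weights must sum to 1")
    logp = log_prob(params, config, list(trees)).data
    nz = w > 0
    return float((w[nz] * (np.log(w[nz]) - logp[nz])).sum())


# ---------------------------------------------------------------------------
# Branch-length model (diagonal lognormal on learnable edge features)
# ---------------------------------------------------------------------------

def init_branch_params(config: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """A small MLP from final-tree edge features to lognormal (mu, log sigma).

    The feature of an edge is the elementwise maximum of the topological
    embedding rows of its two endpoints on the completed tree.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    _mlp_init(params, "branch", rng, config.N, config.hidden, 2, final_ln=False)
    # start near the prior: q ~ exp(mu), push mu toward log(0.1)
    params["branch.b2"].data[0] = np.log(0.1)
    params["branch.b2"].data[1] = -1.0
    return params


def branch_edge_features(topology: Topology) -> tuple[OrdinalTreeState, np.ndarray]:
    """Canonical rank-N state and its (2N-3, N) per-edge feature matrix."""
    st = init_state(topology.taxa)
    for d in decompose(topology):
        st = attach_leaf(st, d)
    F = exact_embedding(st)
    Fbar = pad_embeddings(F, st.n, st.N)
    rows = st.edge_rows()
    feats = np.maximum(Fbar[rows[:, 0]], Fbar[rows[:, 1]])
    return st, feats


def branch_loc_scale(bparams: dict, feats: np.ndarray) -> tuple[Tensor, Tensor]:
    out = _mlp(bparams, "branch", ad.constant(feats))  # (E, 2)
    mu = out[:, 0]
    sigma = out[:, 1].exp()
    return mu, sigma


def branch_sample_logpdf(bparams: dict, feats: np.ndarray, rng,
                         z: np.ndarray | None = None
                         ) -> tuple[Tensor, Tensor]:
    """Reparametrized lognormal draw: q = exp(mu + sigma z), z ~ N(0, 1).

    Returns (q, log density) as differentiable tensors; the log density
    includes the lognormal Jacobian term ``-sum log q``.
    """
    mu, sigma = branch_loc_scale(bparams, feats)
    if z is None:
        z = rng.standard_normal(mu.shape)
    zc = ad.constant(z)
    log_q = mu + sigma * zc
    q = log_q.exp()
    logpdf = (-log_q - sigma.log()
              - 0.5 * np.log(2 * np.pi) - 0.5 * ad.constant(z ** 2)).sum()
    return q, logpdf


# ---------------------------------------------------------------------------
# VBPI
# ---------------------------------------------------------------------------

def vbpi_bound(params: dict, bparams: dict, config: ModelConfig,
               alignment: Alignment, K: int, beta: float, rng) -> dict:
    """K-sample annealed VBPI lower bound and its gradient surrogate.

    Log-weights are ``beta * loglik + log prior - log Q_phi - log Q_psi``;
    topology gradients use VIMCO signals, branch gradients flow through the
    reparametrized samples inside the bound itself.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    trees, logq_topo = sample(params, config, alignment.taxa, K, rng)
    ls = []
    for i, tree in enumerate(trees):
        st, feats = branch_edge_features(tree)
        q, logq_branch = branch_sample_logpdf(bparams, feats, rng)
        topo = st.to_topology()
        loglik = pruning_loglik_t(topo, _align_edge_order(topo, st, q), alignment)
        logpri = (ad.constant(np.log(10.0) * len(st.edges)) - (q * 10.0).sum()
                  - log_double_factorial(2 * config.N - 5))
        ls.append(loglik * beta + logpri - logq_topo[i] - logq_branch)
    l = ad.concat([x.reshape(1) for x in ls], axis=0)
    bound = _log_mean_exp(l)
    if K >= 2:
        signals = vimco_signals(l.data)
        surrogate = -(bound + (ad.constant(signals) * logq_topo).sum())
    else:
        surrogate = -bound
    return {
        "bound": bound.item(),
        "bound_tensor": bound,
        "log_weights": l.data.copy(),
        "topologies": trees,
        "surrogate": surrogate,
    }


def _align_edge_order(topology: Topology, state: OrdinalTreeState,
                      q: Tensor) -> Tensor:
    """Permute a state-edge-ordered branch vector to ``topology.edges`` order."""
    perm = [state.edges.index(e) for e in topology.edges]
    return q[np.asarray(perm, dtype=np.intp)]


def marginal_likelihood_is(params: dict, bparams: dict, config: ModelConfig,
                           alignment: Alignment, n_particles: int,
                           rng) -> float:
    """Importance-sampling estimate of log p(Y) from the variational family."""
    trees, logq_topo = sample(params, config, alignment.taxa, n_particles, rng)
    logw = np.empty(n_particles)
    # group particles by topology so branch draws vectorize
    groups: dict[Topology, list[int]] = {}
    for i, t in enumerate(trees):
        groups.setdefault(t, []).append(i)
    for tree, idx in groups.items():
        st, feats = branch_edge_features(tree)
        topo = st.to_topology()
        mu, sigma = branch_loc_scale(bparams, feats)
        mu_v, sig_v = mu.data, sigma.data
        E = len(st.edges)
        z = rng.standard_normal((len(idx), E))
        log_q = mu_v + sig_v * z
        q = np.exp(log_q)
        perm = [st.edges.index(e) for e in topo.edges]
        loglik = pruning_loglik_batch(topo, q[:, perm], alignment)
        logpri = (-log_double_factorial(2 * config.N - 5)
                  + (np.log(10.0) - 10.0 * q).sum(axis=1))
        logq_branch = (-log_q - np.log(sig_v)
                       - 0.5 * np.log(2 * np.pi) - 0.5 * z ** 2).sum(axis=1)
        logw[idx] = loglik + logpri - logq_topo.data[idx] - logq_branch
    mx = logw.max()
    return float(np.log(np.exp(logw - mx).mean()) + mx)
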