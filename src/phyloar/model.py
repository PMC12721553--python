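"""The autoregressive edge-decision model over tree topologies.

At each leaf-addition step ``n`` the current rank-``n`` trees are embedded by
the fixed-point solver, lifted to ``d``-dimensional node features by a 2-layer
MLP, pooled into a single graph representation with one multi-head attention
query, and scored per edge: an edge's feature is the elementwise maximum of
its endpoint features, concatenated with the graph vector, shifted by the
sinusoidal positional embedding of the step, and read out to a scalar.  The
softmax over the ``2n - 3`` canonical edges is the edge-decision distribution;
the product of the chosen decision probabilities over steps ``3 .. N-1`` is
the model probability of the final topology, normalized over the whole
``(2N - 5)!!`` topology space by construction.

Layer normalization follows every linear layer in the MLPs (except the scalar
output of the edge readout, where it would be degenerate) and precedes the
attention block; a residual connection wraps the attention block.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fixpoint import FixpointConfig, fixpoint_embedding, pad_embeddings
from .treespace import (DecisionSequence, OrdinalTreeState, TaxaOrder, Topology,
                        attach_leaf, decompose, init_state)

__all__ = [
    "ModelConfig",
    "init_params",
    "sinusoidal_embedding",
    "multi_head_attention",
    "graph_representation",
    "edge_log_distribution",
    "sample",
    "log_prob",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``d`` is the node-feature width (default 100) and must be divisible by
    the head count ``h`` (default 4); ``hidden`` is the intermediate width of
    all 2-layer MLPs and defaults to ``d``.  ``epsilon`` is the fixed-point
    stopping tolerance.
    """

    N: int
    d: int = 100
    h: int = 4
    hidden: int | None = None
    epsilon: float = 1e-5
    fixpoint_mode: str = "power"

    def __post_init__(self):
        if self.hidden is None:
            self.hidden = self.d
        if self.d % self.h != 0:
            raise ValueError("d must be divisible by h")
        if self.N < 3:
            raise ValueError("need at least 3 taxa")

    @property
    def fixpoint(self) -> FixpointConfig:
        return FixpointConfig(epsilon=self.epsilon, mode=self.fixpoint_mode)


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int):
    W = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
    return ad.parameter(W), ad.parameter(np.zeros(fan_out))


def _mlp_init(params: dict, name: str, rng, din: int, k: int, dout: int,
              final_ln: bool) -> None:
    params[f"{name}.W1"], params[f"{name}.b1"] = _linear_init(rng, din, k)
    params[f"{name}.g1"] = ad.parameter(np.ones(k))
    params[f"{name}.c1"] = ad.parameter(np.zeros(k))
    params[f"{name}.W2"], params[f"{name}.b2"] = _linear_init(rng, k, dout)
    if final_ln:
        params[f"{name}.g2"] = ad.parameter(np.ones(dout))
        params[f"{name}.c2"] = ad.parameter(np.zeros(dout))


def _mlp(params: dict, name: str, x: Tensor) -> Tensor:
    h = x @ params[f"{name}.W1"] + params[f"{name}.b1"]
    h = ad.layer_norm(h, params[f"{name}.g1"], params[f"{name}.c1"]).elu()
    y = h @ params[f"{name}.W2"] + params[f"{name}.b2"]
    if f"{name}.g2" in params:
        y = ad.layer_norm(y, params[f"{name}.g2"], params[f"{name}.c2"])
    return y


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Fan-in-scaled random initialization of all learnable tensors."""
    rng = np.random.default_rng(seed)
    d, k, N = config.d, config.hidden, config.N
    params: dict[str, Tensor] = {}
    _mlp_init(params, "embed", rng, N, k, d, final_ln=True)
    params["query"] = ad.parameter(rng.normal(0.0, 1.0, size=d))
    for w in ("WQ", "WK", "WV", "WO"):
        params[f"attn.{w}"], _ = _linear_init(rng, d, d)
    params["attn.g"] = ad.parameter(np.ones(d))
    params["attn.c"] = ad.parameter(np.zeros(d))
    _mlp_init(params, "graph", rng, d, k, d, final_ln=True)
    _mlp_init(params, "edge", rng, 2 * d, k, 1, final_ln=False)
    return params


def sinusoidal_embedding(n: int, dim: int) -> np.ndarray:
    """Transformer positional code: (sin, cos) pairs at geometric frequencies."""
    if dim % 2 != 0:
        raise ValueError("dim must be even")
    i = np.arange(dim // 2)
    angle = n / (10_000.0 ** (2.0 * i / dim))
    out = np.empty(dim)
    out[0::2] = np.sin(angle)
    out[1::2] = np.cos(angle)
    return out


def multi_head_attention(Q: Tensor, K: Tensor, V: Tensor,
                         params: dict, h: int) -> Tensor:
    """Scaled dot-product attention with ``h`` heads; inputs (B, *, d)."""
    d = Q.shape[-1]
    dh = d // h
    heads = []
    Qp = Q @ params["attn.WQ"]
    Kp = K @ params["attn.WK"]
    Vp = V @ params["attn.WV"]
    for i in range(h):
        sl = slice(i * dh, (i + 1) * dh)
        scores = (Qp[..., sl] @ Kp[..., sl].swapaxes(-1, -2)) / np.sqrt(dh)
        heads.append(scores.softmax(axis=-1) @ Vp[..., sl])
    return ad.concat(heads, axis=-1) @ params["attn.WO"]


def graph_representation(node_features: Tensor, params: dict,
                         config: ModelConfig) -> Tensor:
    """Attention pooling with a learnable query; (B, R, d) -> (B, 1, d)."""
    B = node_features.shape[0]
    X = ad.layer_norm(node_features, params["attn.g"], params["attn.c"])
    q = params["query"].reshape(1, 1, config.d) + ad.constant(np.zeros((B, 1, config.d)))
    rbar = q + multi_head_attention(q, X, X, params, config.h)
    return _mlp(params, "graph", rbar)


def edge_log_distribution(params: dict, config: ModelConfig,
                          states: Sequence[OrdinalTreeState]) -> Tensor:
    """Log edge-decision probabilities for a batch of equal-rank states.

    Returns a (B, 2n-3) tensor of log probabilities in canonical edge order.
    """
    n = states[0].n
    F, _ = fixpoint_embedding(states, config.fixpoint)
    Fbar = pad_embeddings(F, n, config.N)  # (B, 2n-2, N)
    X = _mlp(params, "embed", ad.constant(Fbar))  # node features (B, 2n-2, d)
    r = graph_representation(X, params, config)  # (B, 1, d)

    rows = np.stack([s.edge_rows() for s in states])  # (B, E, 2)
    p = ad.maximum(X.gather_rows(rows[:, :, 0]), X.gather_rows(rows[:, :, 1]))
    B, E = rows.shape[0], rows.shape[1]
    r_exp = r + ad.constant(np.zeros((B, E, config.d)))
    b_n = ad.constant(sinusoidal_embedding(n, 2 * config.d))
    scores = _mlp(params, "edge", ad.concat([p, r_exp], axis=-1) + b_n)
    return scores.reshape(B, E).log_softmax(axis=-1)


def sample(params: dict, config: ModelConfig, taxa: TaxaOrder, B: int,
           seed: int | np.random.Generator = 0
           ) -> tuple[list[Topology], Tensor]:
    """Draw ``B`` topologies autoregressively; returns (trees, log-probs).

    The returned log-probability tensor is differentiable w.r.t. the model
    parameters (score-function term for VIMCO-style estimators).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = [init_state(taxa) for _ in range(B)]
    logp = ad.constant(np.zeros(B))
    for n in range(3, config.N):
        loga = edge_log_distribution(params, config, states)
        probs = np.exp(loga.data)
        probs /= probs.sum(axis=1, keepdims=True)
        choices = np.array([rng.choice(2 * n - 3, p=probs[b]) for b in range(B)])
        logp = logp + loga[(np.arange(B), choices)]
        states = [attach_leaf(s, int(c)) for s, c in zip(states, choices)]
    return [s.to_topology() for s in states], logp


def log_prob(params: dict, config: ModelConfig,
             topologies: Sequence[Topology]) -> Tensor:
    """Teacher-forced log probability of each topology, batched."""
    decisions = [decompose(t) for t in topologies]
    return log_prob_decisions(params, config, topologies[0].taxa, decisions)


def log_prob_decisions(params: dict, config: ModelConfig, taxa: TaxaOrder,
                       decisions: Sequence[DecisionSequence]) -> Tensor:
    B = len(decisions)
    states = [init_state(taxa) for _ in range(B)]
    logp = ad.constant(np.zeros(B))
    for n in range(3, config.N):
        loga = edge_log_distribution(params, config, states)
        choices = np.array([d[n - 3] for d in decisions])
        logp = logp + loga[(np.arange(B), choices)]
        states = [attach_leaf(s, int(c)) for s, c in zip(states, choices)]
    return logp


def save_checkpoint(path: str, params: dict[str, Tensor],
                    config: ModelConfig) -> None:
    """Serialize parameters (npz) with a YAML config sidecar."""
    import yaml

    np.savez(path, **{k: v.data for k, v in params.items()})
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)


def load_checkpoint(path: str) -> tuple[dict[str, Tensor], ModelConfig]:
    import yaml

    with open(str(path) + ".yaml") as fh:
        config = ModelConfig(**yaml.safe_load(fh))
    arrays = np.load(str(path) if str(path).endswith(".npz") else str(path))
    params = {k: ad.parameter(arrays[k]) for k in arrays.files}
    return params, config
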