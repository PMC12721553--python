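"""Training loops for the three tasks, CPU-first and fully seeded.

Each loop takes an explicit ``numpy`` Generator, records per-iteration
metrics, and mutates the parameter dictionaries in place through Adam.
Desk-scale defaults (small ``d``, thousands of updates, higher learning
rate than the large-scale setting) live with the callers; the loops
themselves are size-agnostic.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .alignment import Alignment
from .model import ModelConfig, log_prob_decisions
from .objectives import (AnnealSchedule, anneal_beta, parsimony_elbo,
                         vbpi_bound)
from .optim import Adam
from .treespace import Topology, decompose
from .autodiff import Tensor

__all__ = ["train_tde", "train_parsimony", "train_vbpi"]

Callback = Callable[[int, dict], None] | None


def train_tde(params: dict[str, Tensor], config: ModelConfig,
              trees: Sequence[Topology], weights, *, steps: int,
              batch_size: int = 10, lr: float = 1e-4, rng=None,
              callback: Callback = None) -> list[dict]:
    """Maximum-likelihood fit to a weighted tree collection."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    decisions = [decompose(t) for t in trees]
    taxa = trees[0].taxa
    opt = Adam(params, lr=lr)
    history = []
    for t in range(steps):
        idx = rng.choice(len(trees), size=batch_size, p=w)
        opt.zero_grad()
        loss = -log_prob_decisions(params, config, taxa,
                                   [decisions[i] for i in idx]).mean()
        loss.backward()
        opt.step()
        rec = {"step": t, "nll": loss.item()}
        history.append(rec)
        if callback:
            callback(t, rec)
    return history


def train_parsimony(params: dict[str, Tensor], config: ModelConfig,
                    alignment: Alignment, *, steps: int, K: int = 10,
                    schedule: AnnealSchedule | None = None, lr: float = 1e-4,
                    rng=None, callback: Callback = None) -> list[dict]:
    """Annealed VIMCO maximization of the K-sample parsimony bound."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    schedule = schedule or AnnealSchedule(period=max(steps // 2, 1))
    opt = Adam(params, lr=lr)
    history = []
    for t in range(steps):
        beta = anneal_beta(t, schedule)
        opt.zero_grad()
        out = parsimony_elbo(params, config, alignment, K, beta, rng)
        out["surrogate"].backward()
        opt.step()
        rec = {"step": t, "beta": beta, "bound": out["bound"],
               "min_score": float(out["scores"].min())}
        history.append(rec)
        if callback:
            callback(t, rec)
    return history


def train_vbpi(params: dict[str, Tensor], bparams: dict[str, Tensor],
               config: ModelConfig, alignment: Alignment, *, steps: int,
               K: int = 10, schedule: AnnealSchedule | None = None,
               lr: float = 1e-4, rng=None, callback: Callback = None
               ) -> list[dict]:
    """Joint topology + branch-length variational fit to the JC posterior."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    schedule = schedule or AnnealSchedule(period=max(steps // 2, 1))
    opt = Adam({**params, **{f"psi::{k}": v for k, v in bparams.items()}}, lr=lr)
    history = []
    for t in range(steps):
        beta = anneal_beta(t, schedule)
        opt.zero_grad()
        out = vbpi_bound(params, bparams, config, alignment, K, beta, rng)
        out["surrogate"].backward()
        opt.step()
        rec = {"step": t, "beta": beta, "bound": out["bound"]}
        history.append(rec)
        if callback:
            callback(t, rec)
    return history
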