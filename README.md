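# phyloar

Autoregressive generative models over phylogenetic tree topologies, with
topological node embeddings computed by a contracting fixed-point iteration
and edge decisions scored by attention-based graph pooling.

## The problem

Bayesian and variational phylogenetics need flexible probability
distributions over the space of leaf-labeled unrooted bifurcating tree
topologies, which grows as (2N−5)!! in the number of taxa N. Classical
estimators (conditional clade distributions, subsplit Bayesian networks)
only put mass on clades seen in a pre-sampled tree set. An autoregressive
construction avoids that restriction: fixing a taxa order x₁,…,x_N, every
topology τ corresponds bijectively to a sequence of edge decisions
e₃,…,e_{N−1} — start from the unique 3-leaf star and, at each rank n,
attach the next leaf to one of the 2n−3 edges of the current tree. The
model defines

  Q_ϕ(τ) = ∏_{n=3}^{N−1} Q_ϕ(e_n | e_{<n}),

a properly normalized distribution with full support on the whole topology
space, where each conditional is a softmax over the current edges.

Per step, each node u of the rank-n tree gets a topological embedding
f(u) ∈ ℝⁿ: leaves are pinned to one-hot vectors and interior embeddings
minimize the Dirichlet energy Σ_{(u,v)∈E} ‖f(u) − f(v)‖². Because interior
nodes have degree 3, the minimizer solves F = AF/3 + C/3 (A = interior
adjacency, C = leaf–interior cross adjacency). The spectral radius of A is
at most 2√2 for *every* tree shape, so Jacobi iteration from the constant
1/n matrix contracts at rate 2√2/3 ≈ 0.943 — the iteration count for a
tolerance ε is a topology-independent constant, and repeated squaring of
the augmented matrix ("power trick") reaches the same iterate in
logarithmically many steps. Embeddings are mapped to d-dimensional node
features by an MLP, pooled into a graph vector by a single learnable
attention query, combined with per-edge features (elementwise max of
endpoint features) and a sinusoidal step embedding, and read out to edge
scores.

Three training objectives are provided:

- **Variational maximum parsimony** — target P(τ) ∝ exp(−S(τ;Y)) with S
  the Fitch parsimony score; annealed K-sample lower bound, VIMCO
  gradients.
- **Tree-topology density estimation (TDE)** — maximum likelihood on a
  weighted tree collection.
- **Variational Bayesian phylogenetic inference (VBPI)** — joint family
  Q_ϕ(τ)Q_ψ(q|τ) against the annealed posterior under the Jukes–Cantor
  substitution model, uniform topology prior and Exp(10) branch-length
  priors; lognormal branch model with reparametrized gradients, and an
  importance-sampling marginal-likelihood estimator.

All numerics run on numpy; gradients come from a compact reverse-mode
autodiff engine included in the package (`phyloar.autodiff`).

## Worked example

`examples/03_density_estimation.py` fits the model to 10,000 trees drawn
from a known target p(τ) ∝ exp(−RF(τ, anchor)) over the 105 six-taxon
topologies and reports the exact KL divergence:

```
target: 105 topologies, entropy 2.731 nats, 105 unique trees observed
KL(target || model) before training: 2.0474
KL(target || model) after 1500 updates: 0.0210
```

The KL is computed against the exact enumerated target, so the 0.021 nats
after training is genuine approximation error (floored near 0.005 nats by
the finite training sample). The other examples cover the fixed-point
solver (`01`), sampling and exact normalization (`02`), variational
parsimony with an exhaustively verified optimum (`04`), and VBPI against a
brute-force evidence computation (`05`); each prints the quantities it
checks and a line on what they mean.

A thin CLI mirrors the library for shell use:

```bash
phyloar train-tde config.yaml        # also: train-parsimony, train-vbpi
phyloar sample --ckpt run/ckpt.npz --n-samples 100 --seed 1 --out trees.nwk
phyloar logprob --ckpt run/ckpt.npz --trees trees.nwk --out scores.tsv
phyloar eval-kl --ckpt run/ckpt.npz --target target.nwk
```

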