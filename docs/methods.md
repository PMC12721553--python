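# Methods

## Model

### Ordinal construction and canonical ordering

A topology on taxa x₀,…,x_{N−1} (lexicographic order by default) is built
by ranks n = 3,…,N: the rank-3 star is unique, and each step subdivides a
chosen edge with a new interior node that also carries the next leaf. The
inverse decomposition peels the highest-indexed leaf at each step; peeling
then replaying reads off the canonical index of each chosen edge, giving a
bijection between topologies and decision sequences.

Node keys are fixed as: leaf i ↦ i, the interior node created at step k ↦
N + (k − 3). Edges are `(min, max)` key pairs sorted lexicographically.
Nothing in the probability model depends on which deterministic order is
used, but sampling and evaluation must share one; this choice makes the
adjacency update on leaf attachment touch O(1) entries beyond the appended
row/column. Topology identity is the set of non-trivial splits, so it is
independent of interior keying and of Newick representation.

### Embeddings

Leaves are pinned to one-hot vectors in ℝⁿ; interior rows of the embedding
matrix F solve (I − A/3)F = C/3, the stationarity condition of the
Dirichlet energy under the degree-3 identity. Useful consequences, both
enforced in tests: every interior row is a probability vector over leaves
(the hitting distribution of a random walk started at that node), and row
sums are exactly 1.

The production solver is the fixed-point iteration F ← AF/3 + C/3 started
from the constant 1/n matrix. Two modes are available:

- **plain** — M_ε matrix products, M_ε precomputed from the contraction
  rate (below);
- **power** — ⌈log₂ M_ε⌉ squarings of the augmented matrix
  [[I, 0], [C/3, A/3]] applied to the stacked start, algebraically equal
  to 2^⌈log₂ M_ε⌉ plain steps.

The direct linear solve is kept as the test oracle (`exact_embedding`);
it is not the production path.

**Stopping rule.** The convergence criterion ‖F^(m) − F*‖/n < ε references
the unknown fixed point, so the implemented default precomputes the
smallest m with (2√2/3)^m √(2(n−2)) ≤ εn. The a-priori initial error bound
√(2(n−2)) uses one factor √2 per interior row: both the start rows and the
fixed-point rows lie in the simplex, whose diameter is √2. The matrix norm
in the criterion is read as Frobenius (it upper-bounds the spectral norm
used in the contraction argument and is cheap to evaluate); ε defaults to
1e-5. Observed contraction ratios on random trees are ≈0.8, comfortably
below the worst-case 2√2/3, so the precomputed count lands far below the
tolerance in practice. An adaptive successive-difference rule was
considered and rejected: the precomputed count is branch-free and keeps
batched iteration fully synchronous.

### Edge-decision network

Per step n, padded embeddings (2n−2 rows, N columns, zero-filled beyond
column n) are mapped by a 2-layer MLP L to d-dimensional node features.
A single learnable query q attends over the layer-normalized features
(h heads, scaled dot product, output projection); a residual connection
adds q back, and a 2-layer MLP produces the graph vector r_n. An edge's
feature is the elementwise maximum of its endpoint features — symmetric in
the endpoints, so storage order is irrelevant. The concatenation
(p_n(e), r_n) ∈ ℝ^{2d} plus the 2d-dimensional sinusoidal embedding of
step n feeds a 2-layer MLP with scalar output; the softmax over the 2n−3
canonical edges is the decision distribution.

Architectural conventions: ELU activations; layer normalization after
every linear layer inside MLPs and immediately before the attention block;
one residual connection around the attention block. Exceptions and
decisions taken where the design was genuinely open:

- the scalar-output layer of the edge readout has no layer norm —
  normalizing a single scalar collapses it to the bias;
- one query vector is shared across steps; step identity enters only
  through the sinusoid. Per-step queries would not transfer across N;
- the residual wraps the attention block only, not the graph readout;
- attention produces only the pooled graph vector; per-node features are
  not rewritten by attention;
- no recurrence across steps: the growing topology plus the positional
  embedding carry all step-to-step memory;
- MLP hidden widths default to d and are configurable.

Defaults are d = 100, h = 4 (d divisible by h required), ε = 1e-5,
Adam with learning rate 1e-4 — the large-scale settings. The desk-scale
runs in the examples, tests, and acceptance script use d = 8–16, h = 2,
learning rate 1e-3 and thousands (not hundreds of thousands) of updates;
these are this package's chosen study conditions for problem sizes where
exhaustive enumeration is available as ground truth.

### Gradients

No autodiff framework is part of the dependency stack, so the package
ships a small reverse-mode engine over numpy arrays (`phyloar.autodiff`)
supporting exactly the operations the model uses. Every operation's
gradient is tested against central differences, and an end-to-end check
verifies the full model loss gradient the same way. Sampling is treated as
a constant path (categorical draws); score-function terms are added
explicitly by the objectives.

## Objectives

**Fitch parsimony.** Per-site state-set dynamic programming with bitmasks,
vectorized over sites, on the tree rooted at leaf 0 (the score is
root-invariant; fixing the root makes runs reproducible). IUPAC ambiguity
codes and gaps become full or partial state sets. Verified against a
brute-force minimum over all internal assignments.

**Annealed parsimony bound.** K topologies are drawn from the model;
log-weights l_i = −β S(τ_i;Y) − log Q_ϕ(τ_i); the bound is their
log-mean-exp. β_t = min{1, 0.001 + t/H}. The VIMCO estimator uses the
leave-one-out baseline that replaces each log-weight by the arithmetic
mean of the others; the surrogate loss adds Σ_i signal_i · log Q_ϕ(τ_i)
to the pathwise bound. Unbiasedness is verified on an enumerable
categorical toy against the exact bound gradient.

**Likelihood.** Felsenstein pruning under Jukes–Cantor with the uniform
stationary distribution at the root (placed at the interior node next to
leaf 0; reversibility makes the placement irrelevant). Three variants
share the recursion: scalar, batched over branch-length vectors, and
differentiable in the branch lengths. Per-site rescaling guards against
underflow in the batched path.

**Priors.** Uniform over the (2N−5)!! topologies; i.i.d. Exp(10) branch
lengths.

**Branch-length model.** A diagonal lognormal whose location and scale
come from a 2-layer MLP on final-tree edge features (elementwise max of
the endpoint embedding rows of the completed tree). This is a deliberately
lightweight parametrization chosen to keep VBPI runnable end to end; it is
initialized near the prior median, and no claim is made that it matches
the accuracy of richer structured branch models on large data sets.
Sampling uses the reparametrization q_e = exp(μ_e + σ_e z_e), so branch
gradients flow through the bound directly.

**Marginal likelihood.** Log-mean-exp of independent importance weights at
β = 1; particles are grouped by sampled topology so branch draws and
likelihoods vectorize.

## Synthetic data

The generators replace external MCMC tree samples and benchmark
alignments with enumerable equivalents, exercising identical code paths:

- `random_topology` draws uniformly over the (2N−5)!! topologies by
  uniform edge decisions (exactly uniform via the decision bijection);
- `toy_target` is p(τ) ∝ exp(−λ·RF(τ, anchor)), normalized exhaustively
  (N ≤ 7), so KL divergences to it are exact, not estimated;
- `simulate_jc_alignment` evolves i.i.d. sites forward under JC with
  branch lengths drawn Exp(10) by default, matching the inference prior.

What these do **not** emulate: MCMC autocorrelation and burn-in artifacts
in tree sets, model misspecification (the simulator matches the likelihood
family), rate heterogeneity, indels, and the taxa counts (27–64) and site
counts of real benchmark alignments. Passing the desk-scale recovery tests
therefore demonstrates correctness of the machinery and optimization at
small N, not approximation quality on real data.

## Study conditions in tests and acceptance runs

- Fixed-point equivalence: 100–200 random trees, n ∈ {4,…,50}, ε = 1e-5,
  both modes, against the direct solve.
- Spectral bound: exhaustive over all states at N ≤ 7 plus random trees up
  to N = 100.
- TDE recovery: N = 6, λ = 1 target, 10⁴ training draws, d = 16, h = 2,
  batch 32, 3000 Adam updates at lr 1e-3; exact KL target < 0.05.
- Parsimony recovery: N = 7, M = 200 JC sites simulated with Exp(5)
  branch lengths (long enough branches to carry signal), unique exhaustive
  optimum over 945 topologies required of the draw; 3000 VIMCO updates,
  K = 10, annealing period 1000.
- VBPI sanity: N = 4, M = 30; evidence by exhaustive topology sum and
  10-point Exp(10)-quantile quadrature per edge; 400 training updates,
  then bound ≤ evidence (within Monte-Carlo error and quadrature bias)
  and IS convergence in the particle count.

## Numerical notes and limitations

- Elementwise-max ties in edge features route gradients to the first
  operand; ties have measure zero under random initialization.
- `enumerate_topologies` refuses N > 8; `toy_target` N > 7.
- Batched model evaluation requires equal N across a batch (equal ranks at
  every step); mixed-N batching is not supported.
- The sampler loops over ranks in Python; per-rank computation is
  vectorized across the batch. CPU-first design; no accelerator path.
- Training runs are deterministic given a seed and single-threaded BLAS;
  across BLAS implementations bit-level results may differ.
- Hypothesis-based property tests run derandomized for reproducibility.
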