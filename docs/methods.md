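# Methods

## Problem setting

The data are a weighted collection T = {(τᵢ, wᵢ)}, Σwᵢ = 1, of unrooted
bifurcating topologies sharing one leaf set X = {x₁, …, x_N}; leaves are
ordered lexicographically by species name (overridable). The package fits
a latent-variable model p_θ(τ) = ∫ p_θ(τ|z) N(z; 0, I_d) dz to the
empirical distribution p_data(τ) = Σᵢ wᵢ δ_τᵢ(τ) and learns a deterministic
per-topology representation μ_τ ∈ ℝᵈ.

## Integer codec

The bijection between topologies and integer vectors is the modelling
substrate. Decomposition removes leaves strictly in reverse leaf order
(x_N first); removing x_n suppresses its attachment node t_n and records
the edge (u, v) joining t_n's two remaining neighbours. Reconstruction
starts from the 3-leaf star (leaves indexed 1–3, centre r unindexed) and
re-attaches x₄…x_N; the recorded edge is oriented away from r (the far
endpoint v_n is always a child in the rooted-at-r parent map, and is never
r itself — the implementation asserts this), s_n = Index(v_n), and the new
nodes get indices Index(t_{n+1}) = N+n−2, Index(x_{n+1}) = n+1.

Two implementation choices make both directions O(N): (i) the working tree
is kept rooted at r with explicit parent pointers, so "farther from r" is a
single pointer comparison, never a path search; (ii) decomposition
remembers the identity of each suppressed attachment node and
reconstruction re-attaches that same node, so recorded edge decisions refer
to nodes that exist at replay time without any relabelling. During
standalone decoding, fresh internal nodes are given their index as their
node id. The degenerate N=3 space has the empty vector as its single
encoding, not an error.

Position n admits exactly the 2n−3 values S_n = {1..n} ∪ {N+1..N+n−3}
(the edges of the rank-n intermediate tree, named by far endpoint);
Π_{n=3}^{N−1} (2n−3) = (2N−5)!! equals the number of topologies, which the
tests verify together with exhaustive round trips for N ≤ 7.

## Generative model

p_θ(τ|z) factorises over encoding positions. A single MLP (two hidden
layers of width 128, ELU; input d, output reshaped to (N−3)×(2N−3)) emits
all position logits in one pass; row n is masked to S_n and softmaxed.
Masking adds −10⁹ to invalid logits inside the differentiable path (safely
below float64 resolution after normalisation), while the evaluation-path
`masked_position_distribution` computes the softmax on the support only, so
off-support probabilities are exactly 0. Column i of the logit matrix
corresponds to node index i (leaves 1..N, then internal N+1..2N−3).
Sampling draws each s_n independently and decodes; argmax mode is
deterministic with ties broken toward the lowest index. Because each masked
row normalises to 1, Σ_τ p_θ(τ|z) = 1 for every z — checked exhaustively on
the five-leaf space.

The hidden width (128) was sized for the N ≤ 8 spaces this package targets
on a single CPU; the architecture is a configuration field
(`decoder_hidden`), not a constant.

## Inference model

Round-0 node features are the unique minimiser of the Dirichlet energy
E(τ) = Σ_{(u,v)∈E} ‖f_u − f_v‖² with leaf rows pinned to the one-hot basis
in leaf order (feature dimension = N). One-hot anchoring makes the
minimiser unique and label-aware. At the minimum every internal row is the
mean of its neighbours' rows; the solution is computed by a two-pass sweep
— post-order elimination expressing f_u = a_u + b_u f_parent, pre-order
back-substitution — in O(N·N) work for the N-dimensional features, and is
tested against a dense linear solve on every tree with N ≤ 6.

A linear layer projects features to hidden width 100, then L = 2 rounds of
synchronous gated message passing f_u ← GRU(f_u, Σ_{v∈N(u)} W_msg f_v)
with per-round message matrices and GRU weights. The graph embedding is
the sum over *all* nodes (leaves and internal), and two single-hidden-layer
MLP heads (width 100, ELU) produce μ_τ and log σ_τ; log σ is clamped to
[−5, 5] to keep importance ratios finite on tiny datasets. Raw round-0
features are projected before the first GRU rather than fed directly, so
the recurrent state width is independent of N.

The pipeline depends only on the abstract adjacency structure, so the
outputs are invariant to internal node relabelling and edge storage order
(tested).

## Training objective

The K-sample bound L_K(τ) = E log(1/K Σᵢ p_θ(τ, zᵢ)/q_φ(zᵢ|τ)) is
estimated with reparameterised particles zᵢ = μ_τ + σ_τ ⊙ εᵢ and computed
in log space via logsumexp; K = 1 recovers the ELBO, and the bound is
monotone non-decreasing in K. Each iteration samples `batch_size`
topologies from p_data with replacement proportionally to their weights and
ascends the batch-mean bound. Gradients flow through a minimal in-package
reverse-mode autodiff over numpy arrays; a finite-difference check with
frozen noise validates them to 1e−4 relative error.

Defaults follow the study protocol where one exists: K = 32 particles,
L = 2 message rounds, batch size 10, latent d ∈ {2, 10}. The optimizer is
a free choice: Adam at learning rate 3e−3 with global gradient-norm
clipping at 100 and no schedule or KL annealing (a config toggle reserves
the latter, defaulting off). 3e−3 was chosen so that desk-scale runs
(tens of thousands of iterations) converge on the enumerable spaces;
encoding vectors and tree tensors of the training set are precomputed once
since the codec and harmonic embeddings are deterministic.

Evaluation estimates log p_θ(τ) by importance sampling with q_φ as
proposal (1000 particles by default); the estimator is unbiased for p_θ(τ)
on the probability scale and hence a stochastic lower bound of the log.
KL(p_data ‖ p_θ) is computed over the reference support,
Σᵢ wᵢ (log wᵢ − log p̂_θ(τᵢ)), and reported with its particle count.

## Synthetic study inputs

The generator reproduces two enumerable-space conditions:

* **Five-leaf Dirichlet task** — all 15 topologies with one weight draw
  w ~ Dirichlet(0.75·1), seeded.
* **Eight-leaf peaked mixture** — three ground-truth topologies drawn
  uniformly without replacement; for each, 500 sites simulated under
  Jukes–Cantor with every edge length fixed at 1; the exact posterior over
  all 10,395 topologies (uniform prior, fixed edge lengths, Felsenstein
  pruning with site-pattern compression) forms one peak; peaks are mixed
  evenly.

JC transition probabilities use the closed form
P(same) = 1/4 + (3/4)e^{−4t/3}, P(diff) = 1/4 − (1/4)e^{−4t/3} — exact and
fast, no rate-matrix exponentiation. The pruning root is the internal node
adjacent to x₁; reversibility makes the likelihood rooting-invariant
(tested). These inputs emulate posterior samples over a *complete* small
tree space with known weights; they do not exercise large leaf sets,
partially observed supports, heterogeneous branch lengths, or MCMC
autocorrelation, so passing tests certify correctness of the machinery and
recoverability of enumerable distributions, not performance on real
posterior samples.

## Problem sizes in the test suite

Training-dependent checks run scaled-down but otherwise under the full
protocol (d = 2, K = 32, batch 10): the five-leaf distribution-recovery
check uses 20,000 iterations and reaches KL ≈ 0.02 nats (threshold 0.05,
1000-particle estimates); the eight-leaf representation check trains 4,000
iterations on the three-peak mixture, at which point the three peaks are
already cleanly separated (silhouette ≈ 0.6) and latent L2 distance
correlates positively with both RF and path-difference distances over the
200 highest-probability trees. These iteration counts are the package's
choice of desk-scale budget for enumerable spaces; longer runs sharpen but
do not change the qualitative picture.

## Numerical and design notes

* Duplicate topologies in a collection are detected by split-set identity
  and merged with summed weights; weights must total 1 within 1e−10.
* Canonical Newick output roots the traversal at the internal node adjacent
  to x₁ with a trifurcation and orders children by smallest contained leaf
  rank, so serialisation is deterministic and diff-friendly. Rooted inputs
  with bifurcating roots are unrooted silently on parse.
* Enumeration inserts leaves in leaf order into every edge of every smaller
  tree, giving a stable topology index; it refuses N > 9.
* The latent grid decodes Gaussian quantiles Φ⁻¹(u) on the interior lattice
  u = k/(R+1), k = 1..R, avoiding infinite endpoints; decoding uses argmax.
* Distance reports use all pairs up to 200 unique trees, otherwise 20,000
  seeded random pairs; classical (Torgerson) MDS of RF distances is
  included only as a plotting baseline and is not part of the model.
* Checkpoints are npz bundles of parameter arrays plus a JSON header
  (format-versioned) holding the config and leaf order.

## Known limitations

* All-Python message passing and a tape-based autodiff keep per-iteration
  cost in the low milliseconds for N ≤ 8 but have not been profiled for
  DS-scale leaf counts (N ≈ 30–60); the architecture supports them, the
  wall-clock budget may not.
* The importance-sampling log-marginal is a lower bound in expectation;
  KL values computed from it are correspondingly conservative (slightly
  inflated), which is the safe direction for the recovery checks.
* No support for rooted-topology modelling, multifurcations, or
  amortisation across leaf sets.
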