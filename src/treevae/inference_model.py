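"""Inference model q(z|τ): topological embeddings, message passing, heads.

Round-0 node features are the unique minimiser of the Dirichlet energy
E(τ) = Σ_{(u,v)∈E} ||f_u - f_v||² with leaf embeddings pinned to the one-hot
basis in leaf order (so the feature dimension equals the leaf count N).  At
the minimiser every internal node's embedding is the average of its
neighbours'; it is computed exactly by a two-pass (post-order accumulation,
pre-order correction) sweep in O(N) rather than a generic linear solve.

The learnable part projects the round-0 features to a hidden width, runs L
synchronous rounds of gated message passing
``f_u^{l+1} = GRU(f_u^l, Σ_{v∈N(u)} W_msg^l f_v^l)`` with per-round weights,
sum-pools over all nodes, and maps the pooled vector through two MLP heads
to the mean and log standard deviation of a diagonal Gaussian.  μ_τ is the
tree's latent representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import MLP, GRUCell, Linear, Module
from .trees import TreeTopology

__all__ = [
    "topological_embeddings",
    "tree_tensors",
    "InferenceModel",
    "PosteriorParams",
    "posterior_params",
    "sample_posterior",
    "lp_distance",
    "dirichlet_energy",
]

LOG_SIGMA_BOUND = 5.0  # |log σ| clamp, guards against posterior collapse blow-ups


def _node_order(topology: TreeTopology) -> List[int]:
    """Canonical node order: leaves by rank, then internal nodes by id."""
    return topology.leaves + topology.internal_nodes


def topological_embeddings(topology: TreeTopology, return_order: bool = False):
    """Dirichlet-energy-minimising node embeddings, shape (2N-2, N).

    Rows follow the canonical node order (leaves by rank, then internal
    nodes); leaf rows are the one-hot basis, internal rows the harmonic
    extension (each equals the mean of its neighbours' rows).
    """
    n = topology.n_leaves
    order = _node_order(topology)
    pos = {u: i for i, u in enumerate(order)}
    leaves = set(topology.leaf_labels)

    # root the sweep at the internal node adjacent to x1
    root = next(iter(topology.adjacency[topology.leaves[0]]))
    parent: Dict[int, Optional[int]] = {root: None}
    dfs = [root]
    topo_order: List[int] = []
    while dfs:
        u = dfs.pop()
        topo_order.append(u)
        for v in topology.adjacency[u]:
            if v not in parent:
                parent[v] = u
                dfs.append(v)

    a = np.zeros((len(order), n))
    b = np.zeros(len(order))
    # post-order accumulation: f_u = a_u + b_u * f_parent
    for u in reversed(topo_order):
        i = pos[u]
        if u in leaves:
            a[i, topology.leaf_rank(u) - 1] = 1.0
            continue
        kids = [v for v in topology.adjacency[u] if v != parent[u]]
        deg = len(topology.adjacency[u])
        sb = sum(b[pos[v]] for v in kids)
        sa = a[[pos[v] for v in kids]].sum(axis=0)
        denom = deg - sb
        if u == root:
            a[i] = sa / denom  # no parent term; deg == number of kids
            b[i] = 0.0
        else:
            a[i] = sa / denom
            b[i] = 1.0 / denom

    f = np.zeros((len(order), n))
    # pre-order correction: substitute the parent's final value
    for u in topo_order:
        i = pos[u]
        p = parent[u]
        f[i] = a[i] if p is None else a[i] + b[i] * f[pos[p]]
    if return_order:
        return f, order
    return f


def dirichlet_energy(topology: TreeTopology, embeddings: np.ndarray) -> float:
    """E(τ) = Σ_{(u,v)∈E} ||f_u - f_v||² for embeddings in canonical order."""
    order = _node_order(topology)
    pos = {u: i for i, u in enumerate(order)}
    total = 0.0
    for u, vs in topology.adjacency.items():
        for v in vs:
            if u < v:
                d = embeddings[pos[u]] - embeddings[pos[v]]
                total += float(d @ d)
    return total


def tree_tensors(topology: TreeTopology) -> Tuple[np.ndarray, np.ndarray]:
    """(round-0 embeddings, adjacency matrix) in canonical node order."""
    f0, order = topological_embeddings(topology, return_order=True)
    pos = {u: i for i, u in enumerate(order)}
    m = len(order)
    adj = np.zeros((m, m))
    for u, vs in topology.adjacency.items():
        for v in vs:
            adj[pos[u], pos[v]] = 1.0
    return f0, adj


@dataclass
class PosteriorParams:
    """Diagonal Gaussian q(z|τ): mean (the representation) and scale."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have the same shape")
        if not np.all(self.sigma > 0):
            raise ValueError("sigma must be strictly positive")


class InferenceModel(Module):
    """Learnable part ϕ of the encoder."""

    def __init__(
        self,
        n_leaves: int,
        latent_dim: int,
        hidden: int = 100,
        rounds: int = 2,
        rng: Optional[np.random.Generator] = None,
    ):
        if rounds < 0:
            raise ValueError("rounds must be >= 0")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_leaves = n_leaves
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.rounds = rounds
        self.proj = Linear(n_leaves, hidden, rng)
        self.msg = [Linear(hidden, hidden, rng) for _ in range(rounds)]
        self.gru = [GRUCell(hidden, hidden, rng) for _ in range(rounds)]
        self.head_mu = MLP([hidden, hidden, latent_dim], rng)
        self.head_log_sigma = MLP([hidden, hidden, latent_dim], rng)

    def message_passing(self, h: Tensor, adj: Tensor) -> Tensor:
        """L synchronous gated rounds over (..., nodes, hidden) states."""
        for w_msg, gru in zip(self.msg, self.gru):
            messages = adj @ w_msg(h)
            h = gru(messages, h)
        return h

    def forward(self, f0: Tensor, adj: Tensor) -> Tuple[Tensor, Tensor]:
        """(μ, log σ) for batched trees: f0 (..., nodes, N), adj (..., n, n)."""
        h = self.proj(f0)
        h = self.message_passing(h, adj)
        pooled = h.sum(axis=-2)  # sum over every node of V
        mu = self.head_mu(pooled)
        log_sigma = self.head_log_sigma(pooled).clip(-LOG_SIGMA_BOUND, LOG_SIGMA_BOUND)
        return mu, log_sigma


def posterior_params(topology: TreeTopology, model: InferenceModel) -> PosteriorParams:
    """Deterministic (μ_τ, σ_τ) for one topology."""
    if topology.n_leaves != model.n_leaves:
        raise ValueError("topology leaf count does not match model")
    f0, adj = tree_tensors(topology)
    with no_grad():
        mu, log_sigma = model.forward(Tensor(f0), Tensor(adj))
    return PosteriorParams(mu.numpy(), np.exp(log_sigma.numpy()))


def sample_posterior(pp: PosteriorParams, n_samples: int, seed: int = 0):
    """Reparameterised draws z_i = μ + σ⊙ε_i with their log-densities."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    d = pp.mu.shape[-1]
    eps = rng.standard_normal((n_samples, d))
    z = pp.mu + pp.sigma * eps
    log_q = (
        -0.5 * d * np.log(2 * np.pi)
        - np.sum(np.log(pp.sigma))
        - 0.5 * (eps**2).sum(axis=-1)
    )
    return z, log_q


def lp_distance(a: PosteriorParams, b: PosteriorParams, p: float = 2.0) -> float:
    """D_Lp(τ1, τ2) = ||μ_τ1 - μ_τ2||_p."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if a.mu.shape != b.mu.shape:
        raise ValueError("latent dimensions differ")
    return float(np.linalg.norm(a.mu - b.mu, ord=p))
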