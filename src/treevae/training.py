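"""IWAE training of the topology VAE and evaluation utilities.

The objective is the K-sample importance-weighted bound

    L_K(τ) = E log( (1/K) Σ_i p(τ, z_i) / q(z_i|τ) ),   z_i ~ q(z|τ),

averaged over the weighted data distribution p_data.  Gradients flow through
the reparameterisation z_i = μ_τ + σ_τ ⊙ ε_i; with K = 1 the bound is the
standard ELBO, and it is monotone non-decreasing in K.  Training samples
batches from p_data with replacement proportionally to the tree weights and
follows Adam on the negated batch-mean bound.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import codec
from .autodiff import Tensor, logsumexp, no_grad
from .generative_model import GenerativeModel
from .inference_model import InferenceModel, tree_tensors
from .nn import Adam
from .trees import TreeCollection, TreeTopology

__all__ = [
    "TrainingConfig",
    "ModelBundle",
    "importance_log_weights",
    "multi_sample_bound",
    "train",
    "kl_to_reference",
]

CHECKPOINT_FORMAT = 1


@dataclass
class TrainingConfig:
    """Hyperparameters.  Defaults follow the study protocol (K=32 particles,
    L=2 message rounds, batches of 10); iteration counts are set per run."""

    latent_dim: int = 2
    n_particles: int = 32
    message_rounds: int = 2
    batch_size: int = 10
    n_iterations: int = 200_000
    learning_rate: float = 3e-3
    seed: int = 0
    log_every: int = 100
    decoder_hidden: Tuple[int, ...] = (128, 128)
    gnn_hidden: int = 100
    clip_norm: float = 100.0
    kl_annealing: bool = False  # reserved toggle; off by default

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.decoder_hidden = tuple(self.decoder_hidden)


@dataclass
class ModelBundle:
    """Generative + inference model pair with their shared configuration."""

    generative: GenerativeModel
    inference: InferenceModel
    config: TrainingConfig
    leaf_order: List[str]

    @classmethod
    def create(cls, leaf_order: Sequence[str], config: Optional[TrainingConfig] = None) -> "ModelBundle":
        config = config or TrainingConfig()
        n = len(leaf_order)
        rng = np.random.default_rng(config.seed)
        gen = GenerativeModel(n, config.latent_dim, hidden=config.decoder_hidden, rng=rng)
        inf = InferenceModel(
            n, config.latent_dim, hidden=config.gnn_hidden, rounds=config.message_rounds, rng=rng
        )
        return cls(gen, inf, config, list(leaf_order))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def parameters(self) -> Dict[str, Tensor]:
        out = {f"gen.{k}": v for k, v in self.generative.parameters().items()}
        out.update({f"inf.{k}": v for k, v in self.inference.parameters().items()})
        return out

    # -- checkpoint I/O ----------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "format": CHECKPOINT_FORMAT,
            "leaf_order": self.leaf_order,
            "config": asdict(self.config),
        }
        arrays = {k: v.data for k, v in self.parameters().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "ModelBundle":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unsupported checkpoint format: {meta.get('format')}")
            cfg = TrainingConfig(**meta["config"])
            bundle = cls.create(meta["leaf_order"], cfg)
            params = bundle.parameters()
            for k, t in params.items():
                t.data = np.array(npz[k], dtype=np.float64)
        return bundle


# ---------------------------------------------------------------------------
# the shared IWAE forward pass


def _collection_tensors(
    bundle: ModelBundle, topologies: Sequence[TreeTopology]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-tree cached inputs: encoding columns, round-0 features, adjacency."""
    s_cols, f0s, adjs = [], [], []
    for t in topologies:
        if list(t.leaf_order) != bundle.leaf_order:
            raise ValueError("tree leaf order does not match bundle")
        s_cols.append(np.asarray(codec.encode(t), dtype=np.intp) - 1)
        f0, adj = tree_tensors(t)
        f0s.append(f0)
        adjs.append(adj)
    return np.stack(s_cols), np.stack(f0s), np.stack(adjs)


def _log_weights_from_tensors(
    bundle: ModelBundle,
    s_cols: np.ndarray,
    f0: np.ndarray,
    adj: np.ndarray,
    eps: np.ndarray,
) -> Tensor:
    """log w_ik = log p(τ_i|z_ik) + log p(z_ik) - log q(z_ik|τ_i), (B, K)."""
    d = bundle.config.latent_dim
    batch, n_particles = eps.shape[0], eps.shape[1]
    mu, log_sigma = bundle.inference.forward(Tensor(f0), Tensor(adj))  # (B, d)
    sigma = log_sigma.exp()
    z = mu.reshape(batch, 1, d) + sigma.reshape(batch, 1, d) * Tensor(eps)  # (B, K, d)
    log_p_tau = bundle.generative.log_prob_encoding(s_cols[:, None, :], z)  # (B, K)
    const = 0.5 * d * math.log(2 * math.pi)
    log_p_z = (z * z).sum(axis=-1) * (-0.5) - const
    log_q = (
        log_sigma.sum(axis=-1).reshape(batch, 1) * (-1.0)
        - Tensor(0.5 * (eps**2).sum(axis=-1))
        - const
    )
    return log_p_tau + log_p_z - log_q


def importance_log_weights(
    generative: GenerativeModel,
    inference: InferenceModel,
    topologies: Sequence[TreeTopology],
    n_particles: int,
    seed: int,
) -> Tensor:
    """(B, K) log importance weights for externally supplied models."""
    bundle = ModelBundle(
        generative,
        inference,
        TrainingConfig(latent_dim=generative.latent_dim, n_particles=n_particles),
        # leaf order is taken from the topologies themselves
        list(topologies[0].leaf_order),
    )
    s_cols, f0, adj = _collection_tensors(bundle, topologies)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((len(topologies), n_particles, generative.latent_dim))
    return _log_weights_from_tensors(bundle, s_cols, f0, adj, eps)


def multi_sample_bound(
    bundle: ModelBundle, topology: TreeTopology, n_particles: Optional[int] = None, seed: int = 0
) -> float:
    """One draw of the K-sample bound L_K(τ) in nats (K=1: the ELBO)."""
    k = bundle.config.n_particles if n_particles is None else n_particles
    if k < 1:
        raise ValueError("n_particles must be >= 1")
    s_cols, f0, adj = _collection_tensors(bundle, [topology])
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((1, k, bundle.config.latent_dim))
    with no_grad():
        lw = _log_weights_from_tensors(bundle, s_cols, f0, adj, eps)
        bound = logsumexp(lw, axis=-1) - math.log(k)
    val = float(bound.numpy()[0])
    if not np.isfinite(val):
        raise FloatingPointError(
            f"non-finite bound (lw range [{lw.numpy().min()}, {lw.numpy().max()}])"
        )
    return val


# ---------------------------------------------------------------------------
# training


def train(
    bundle: ModelBundle,
    data: TreeCollection,
    n_iterations: Optional[int] = None,
    callback=None,
) -> List[Dict[str, float]]:
    """Optimise the bundle on a weighted collection; returns the metrics log.

    Each iteration draws ``batch_size`` topologies from p_data (weighted,
    with replacement), K particles per topology, and ascends the batch-mean
    multi-sample bound.  Fully deterministic given ``config.seed``.
    """
    if len(data) == 0:
        raise ValueError("empty tree collection")
    cfg = bundle.config
    iters = cfg.n_iterations if n_iterations is None else n_iterations
    tops = data.topologies
    weights = data.weights
    s_cols, f0, adj = _collection_tensors(bundle, tops)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(bundle.parameters(), lr=cfg.learning_rate, clip_norm=cfg.clip_norm)
    metrics: List[Dict[str, float]] = []
    t0 = time.perf_counter()
    for it in range(1, iters + 1):
        idx = rng.choice(len(tops), size=cfg.batch_size, p=weights)
        eps = rng.standard_normal((cfg.batch_size, cfg.n_particles, cfg.latent_dim))
        lw = _log_weights_from_tensors(bundle, s_cols[idx], f0[idx], adj[idx], eps)
        bound = logsumexp(lw, axis=-1) - math.log(cfg.n_particles)
        loss = -bound.mean()
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"NaN/inf loss at iteration {it}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if it % cfg.log_every == 0 or it == iters:
            rec = {"iteration": it, "bound": -loss.item(), "seconds": time.perf_counter() - t0}
            metrics.append(rec)
            if callback is not None:
                callback(rec)
    return metrics


# ---------------------------------------------------------------------------
# evaluation


def kl_to_reference(
    bundle: ModelBundle,
    reference: TreeCollection,
    n_particles: int = 1000,
    seed: int = 0,
) -> Dict[str, object]:
    """KL(p_ref || p_model) over the reference support, in nats.

    Model probabilities are importance-sampling estimates with
    ``n_particles`` particles per topology; returns the divergence together
    with per-tree log-probability estimates and the particle count."""
    from .generative_model import marginal_log_prob

    weights = reference.weights
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("reference weights must sum to 1")
    log_probs = []
    offenders = []
    for i, (topology, _) in enumerate(reference):
        lp = marginal_log_prob(
            bundle.generative, bundle.inference, topology,
            n_particles=n_particles, seed=(seed + 7919 * i) % (2**31 - 1),
        )
        if not np.isfinite(lp):
            offenders.append(i)
        log_probs.append(lp)
    log_probs_arr = np.array(log_probs)
    if offenders:
        kl = float("inf")
    else:
        kl = float(np.sum(weights * (np.log(np.maximum(weights, 1e-300)) - log_probs_arr)))
    return {
        "kl": kl,
        "log_probs": log_probs_arr,
        "n_particles": n_particles,
        "zero_probability_trees": offenders,
    }
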