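"""Non-autoregressive generative model over tree topologies.

A latent vector z is mapped by an MLP to a logits matrix with one row per
encoding-vector position n = 3..N-1 and one column per node index
1..2N-3.  Each row, masked to the admissible index set S_n, defines an
independent categorical distribution over s_n; the product of the N-3
categoricals is p(τ|z) through the bijective codec.  Because positions are
conditionally independent given z, one forward pass yields every position's
distribution (no sequential decoding).

Column j (0-based) of the logits matrix corresponds to node index j+1
(leaves 1..N, internal nodes N+1..2N-3).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np

from . import codec
from .autodiff import Tensor, log_softmax, no_grad
from .nn import MLP, Module
from .trees import TreeTopology

__all__ = [
    "GenerativeModel",
    "build_mask",
    "masked_position_distribution",
    "log_prob_given_z",
    "sample_topology",
    "marginal_log_prob",
]

MASK_NEG = -1e9  # additive stand-in for -inf; vanishes exactly after softmax


def build_mask(n_leaves: int) -> np.ndarray:
    """(N-3, 2N-3) additive mask: 0 on S_n, MASK_NEG elsewhere."""
    rows = n_leaves - 3
    cols = 2 * n_leaves - 3
    mask = np.full((rows, cols), MASK_NEG)
    for row in range(rows):
        for idx in codec.allowed_index_set(row + 3, n_leaves):
            mask[row, idx - 1] = 0.0
    return mask


class GenerativeModel(Module):
    """Decoder network θ: z -> logits matrix, plus the fixed position masks."""

    def __init__(
        self,
        n_leaves: int,
        latent_dim: int,
        hidden: Sequence[int] = (128, 128),
        rng: Optional[np.random.Generator] = None,
    ):
        if n_leaves < 3:
            raise ValueError("need at least 3 leaves")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_leaves = n_leaves
        self.latent_dim = latent_dim
        self.hidden = tuple(hidden)
        self.rows = n_leaves - 3
        self.cols = 2 * n_leaves - 3
        self.mlp = MLP([latent_dim, *hidden, self.rows * self.cols], rng)
        self.mask = build_mask(n_leaves)

    def logits(self, z: Tensor) -> Tensor:
        """Unmasked logits matrix Φ(z), shape (..., N-3, 2N-3)."""
        if z.shape[-1] != self.latent_dim:
            raise ValueError(f"z has dim {z.shape[-1]}, model expects {self.latent_dim}")
        out = self.mlp(z)
        return out.reshape(*z.shape[:-1], self.rows, self.cols)

    def log_position_probs(self, z: Tensor) -> Tensor:
        """Masked per-position log-probabilities, shape (..., N-3, 2N-3)."""
        return log_softmax(self.logits(z) + Tensor(self.mask), axis=-1)

    def log_prob_encoding(self, s_columns: np.ndarray, z: Tensor) -> Tensor:
        """log p(s|z) for 0-based column indices ``s_columns`` (..., N-3).

        The leading shape of ``s_columns`` must broadcast against z's leading
        shape.  One decoder forward pass covers all positions.
        """
        logp = self.log_position_probs(z)  # (..., R, C)
        idx = np.broadcast_to(s_columns, logp.shape[:-1])
        return logp.gather_last(idx).sum(axis=-1)


def decoder_logits(model: GenerativeModel, z: Union[np.ndarray, Tensor]) -> np.ndarray:
    """Convenience: unmasked logits as a plain array (evaluation path)."""
    with no_grad():
        return model.logits(Tensor(np.asarray(z, dtype=float))).numpy()


def masked_position_distribution(logits_row: np.ndarray, n: int, n_leaves: int) -> np.ndarray:
    """Probability vector over node indices 1..2N-3 for position n.

    Exactly zero outside S_n; softmax of the logits restricted to S_n inside.
    """
    logits_row = np.asarray(logits_row, dtype=float)
    if logits_row.shape != (2 * n_leaves - 3,):
        raise ValueError(f"expected row of length {2 * n_leaves - 3}")
    support = sorted(codec.allowed_index_set(n, n_leaves))
    cols = [i - 1 for i in support]
    sub = logits_row[cols]
    sub = np.exp(sub - sub.max())
    probs = np.zeros_like(logits_row)
    probs[cols] = sub / sub.sum()
    return probs


def _encoding_columns(topology: TreeTopology) -> np.ndarray:
    return np.asarray(codec.encode(topology), dtype=np.intp) - 1


def log_prob_given_z(model: GenerativeModel, topology: TreeTopology, z: np.ndarray) -> float:
    """log p(τ|z) = Σ_n log p(s_n|z); 0 for N=3 (empty encoding)."""
    if topology.n_leaves != model.n_leaves:
        raise ValueError("topology leaf count does not match model")
    if model.rows == 0:
        return 0.0
    with no_grad():
        lp = model.log_prob_encoding(_encoding_columns(topology), Tensor(np.asarray(z, dtype=float)))
    return float(lp.numpy())


def sample_topology(
    model: GenerativeModel,
    z: np.ndarray,
    labels: Sequence[str],
    mode: str = "sample",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TreeTopology:
    """Draw (or argmax) each s_n independently from its masked categorical
    and decode.  ``mode='argmax'`` is deterministic; ties break to the lowest
    index.  The mask guarantees every sampled vector is a valid encoding."""
    if mode not in ("sample", "argmax"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(labels) != model.n_leaves:
        raise ValueError("label count does not match model")
    logits = decoder_logits(model, np.asarray(z, dtype=float))
    s: List[int] = []
    if mode == "sample" and rng is None:
        rng = np.random.default_rng(seed)
    for row in range(model.rows):
        n = row + 3
        probs = masked_position_distribution(logits[row], n, model.n_leaves)
        if mode == "argmax":
            s.append(int(np.argmax(probs)) + 1)
        else:
            s.append(int(rng.choice(len(probs), p=probs)) + 1)
    return codec.decode(s, labels)


def marginal_log_prob(
    model: GenerativeModel,
    inference,
    topology: TreeTopology,
    n_particles: int = 1000,
    seed: int = 0,
) -> float:
    """Importance-sampling estimate of log p(τ).

    log( (1/K) Σ_i p(τ, z_i) / q(z_i|τ) ) with z_i ~ q(z|τ).  Unbiased for
    p(τ) on the probability scale, hence a stochastic lower bound of
    log p(τ) in expectation.
    """
    from .training import importance_log_weights  # local import to avoid cycle

    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    with no_grad():
        lw = importance_log_weights(model, inference, [topology], n_particles, seed)
    lw = lw.numpy()[0]
    m = lw.max()
    return float(m + np.log(np.mean(np.exp(lw - m))))
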