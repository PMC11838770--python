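"""Neural-network building blocks on top of :mod:`treevae.autodiff`.

Layers hold named parameter tensors; a :class:`Module` exposes them as a
flat ``{name: Tensor}`` dict for the optimizer and for checkpointing.
Initialisation is Glorot-uniform for weight matrices and zero for biases,
drawn from an explicit numpy Generator so model construction is seedable.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "MLP", "GRUCell", "Adam"]


class Module:
    """Base class: recursively collects parameters of attribute sub-modules."""

    def parameters(self) -> Dict[str, Tensor]:
        out: Dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, t in val.parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, t in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
        return out

    def zero_grad(self) -> None:
        for t in self.parameters().values():
            t.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, t in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Feed-forward net with ELU hidden activations and linear output."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).elu()
        return self.layers[-1](x)


class GRUCell(Module):
    """Gated recurrent unit: h' = (1-u)*h + u*tanh(Wc x + Uc (r*h) + bc)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.Wr = Tensor(_glorot(rng, d_in, d_hidden), requires_grad=True)
        self.Ur = Tensor(_glorot(rng, d_hidden, d_hidden), requires_grad=True)
        self.br = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.Wu = Tensor(_glorot(rng, d_in, d_hidden), requires_grad=True)
        self.Uu = Tensor(_glorot(rng, d_hidden, d_hidden), requires_grad=True)
        self.bu = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.Wc = Tensor(_glorot(rng, d_in, d_hidden), requires_grad=True)
        self.Uc = Tensor(_glorot(rng, d_hidden, d_hidden), requires_grad=True)
        self.bc = Tensor(np.zeros(d_hidden), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        u = (x @ self.Wu + h @ self.Uu + self.bu).sigmoid()
        c = (x @ self.Wc + (r * h) @ self.Uc + self.bc).tanh()
        return (1.0 - u) * h + u * c


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(
        self,
        params: Dict[str, Tensor],
        lr: float = 3e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 100.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for k, p in self.params.items()}
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
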