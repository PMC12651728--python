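"""Small neural-network toolkit on top of the autodiff engine.

Provides linear layers, parameter containers, the AdamW optimizer with a
cosine learning-rate schedule, and global-norm gradient clipping — the
training machinery shared by the contrastive encoder and the fusion model.
"""

from __future__ import annotations

import hashlib
import math

import numpy as np

from ._autodiff import Tensor

__all__ = ["Linear", "Module", "AdamW", "cosine_lr", "clip_grad_norm", "params_hash"]


class Module:
    """Base class: parameters are discovered recursively by attribute walk."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
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
                            out[f"{name}[{i}].{sub}"] = t
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in state.items():
            params[k].data[...] = v


class Linear(Module):
    """Dense layer with Glorot-uniform init from a caller-supplied generator."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class AdamW:
    """AdamW with decoupled weight decay on a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1 ** self.t)
            vhat = self._v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def cosine_lr(base_lr: float, epoch: int, total_epochs: int,
              min_lr_frac: float = 0.01) -> float:
    """Cosine annealing from base_lr down to min_lr_frac * base_lr."""
    if total_epochs <= 1:
        return base_lr
    frac = 0.5 * (1.0 + math.cos(math.pi * epoch / (total_epochs - 1)))
    return base_lr * (min_lr_frac + (1.0 - min_lr_frac) * frac)


def clip_grad_norm(params: dict[str, Tensor], max_norm: float = 1.0) -> float:
    """Scale all gradients so their joint L2 norm is at most max_norm."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return norm


def params_hash(state: dict[str, np.ndarray]) -> str:
    """Deterministic content hash of a parameter state dict (frozen-weight audits)."""
    h = hashlib.sha256()
    for k in sorted(state):
        h.update(k.encode())
        h.update(np.ascontiguousarray(state[k]).tobytes())
    return h.hexdigest()
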