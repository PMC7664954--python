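"""Adam with decoupled-from-nothing classic L2 weight decay (added to the
gradient) and global-norm gradient clipping."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam", "clip_global_norm"]


def clip_global_norm(layers: list[Layer], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = 0.0
    for layer in layers:
        for g in layer.grads.values():
            total += float(np.sum(g**2))
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for layer in layers:
            for g in layer.grads.values():
                g *= scale
    return norm


class Adam:
    def __init__(
        self,
        layers: list[Layer],
        lr: float = 5e-3,
        weight_decay: float = 1e-5,
        clip_norm: float | None = 1.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layers = layers
        self.lr = lr
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        if self.clip_norm is not None:
            clip_global_norm(self.layers, self.clip_norm)
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for key, p in layer.params.items():
                g = layer.grads[key]
                if self.weight_decay:
                    g = g + self.weight_decay * p
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g**2
                p -= self.lr * (m[key] / bias1) / (np.sqrt(v[key] / bias2) + self.eps)
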