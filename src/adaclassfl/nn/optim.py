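"""Optimization: AdamW with decoupled weight decay, global-norm gradient
clipping, and the warm-up + step-decay learning-rate schedule used for
federated local training."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "clip_grad_norm", "warmup_step_lr"]


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``.

    Returns the pre-clipping norm.
    """
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class AdamW:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def warmup_step_lr(base_lr: float, step: int, total_steps: int,
                   warmup_frac: float = 0.1, decay: float = 0.5,
                   milestones=(0.75, 0.9)) -> float:
    """Linear warm-up over the first ``warmup_frac`` of steps, then a
    multiplicative ``decay`` at each milestone fraction of the run."""
    warm = max(1, int(round(warmup_frac * total_steps)))
    if step < warm:
        return base_lr * (step + 1) / warm
    lr = base_lr
    for ms in milestones:
        if step >= ms * total_steps:
            lr *= decay
    return lr
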