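"""Adam optimizer with the conventional defaults."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def linear_decay_lr(base_lr: float, epoch: int, epochs_constant: int, epochs_decay: int) -> float:
    """Constant phase followed by linear decay to zero.

    The returned rate is the one used *during* ``epoch`` (0-based); it
    reaches zero only once the decay phase is complete.
    """
    if epoch < epochs_constant:
        return base_lr
    if epochs_decay <= 0:
        return base_lr
    frac = (epoch - epochs_constant) / epochs_decay
    return base_lr * max(0.0, 1.0 - frac)
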