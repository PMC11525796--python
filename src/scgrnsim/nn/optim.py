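"""AMSGrad optimizer with an exponentially decaying learning rate."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class AMSGrad:
    """Adam variant keeping the running maximum of the second moment.

    Defaults follow the training recipe used throughout the package:
    beta1 = 0.5, beta2 = 0.9, and a step-wise exponential learning-rate decay
    (multiply by ``lr_decay`` every ``decay_every`` updates).
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.5, 0.9),
        eps: float = 1e-8,
        lr_decay: float = 0.99,
        decay_every: int = 1000,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.lr_decay = lr_decay
        self.decay_every = max(int(decay_every), 1)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vhat = [np.zeros_like(p.data) for p in self.params]

    @property
    def current_lr(self) -> float:
        return self.lr * self.lr_decay ** (self.t // self.decay_every)

    def step(self) -> None:
        """Apply one update from the ``.grad`` fields of the parameters."""
        lr_t = self.current_lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
            mhat = self.m[i] / bias1
            vhat = self.vhat[i] / bias2
            p.data -= lr_t * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
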