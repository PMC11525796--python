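"""Network building blocks: dense / masked-dense layers, batch norm, LSN.

Initialization policy: He initialization for layers feeding a ReLU, Xavier
(Glorot) for linear-output layers.  Batch normalization is used on generator
and labeler hidden layers but never in the critic, where it would couple the
per-sample input gradients that the gradient penalty constrains.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter collection plus a train/eval switch."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module (parameters + running statistics)."""
        out = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                out.extend([m.running_mean, m.running_var])
        return out

    training: bool = True


class Linear(Module):
    """Affine layer ``y = x W + b`` with He or Xavier initialization."""

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator,
                 init: str = "he"):
        if init == "he":
            std = np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, size=(fan_in, fan_out))
        elif init == "xavier":
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        else:  # pragma: no cover
            raise ValueError(f"unknown init {init!r}")
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(fan_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias


class MaskedLinear(Module):
    """Affine layer whose effective weight is ``W * mask`` at all times.

    The mask is applied in the forward pass, so masked entries contribute
    nothing to the output and, by the chain rule, receive exactly zero
    gradient; together with zero initialization of masked entries the raw
    weights stay zero after any number of optimizer steps.  Per-unit fan-in
    (the number of unmasked inputs) is used for the He scale so sparse units
    are not under-initialized.
    """

    def __init__(self, mask: np.ndarray, rng: np.random.Generator):
        mask = np.asarray(mask, dtype=np.float64)
        fan_in_per_unit = np.maximum(mask.sum(axis=0), 1.0)  # per output unit
        std = np.sqrt(2.0 / fan_in_per_unit)  # He, ReLU layers only
        w = rng.normal(0.0, 1.0, size=mask.shape) * std[None, :]
        self.weight = Tensor(w * mask, requires_grad=True)
        self.bias = Tensor(np.zeros(mask.shape[1]), requires_grad=True)
        self.mask = Tensor(mask)  # constant

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight * self.mask) + self.bias

    @property
    def effective_weight(self) -> np.ndarray:
        return self.weight.data * self.mask.data


class BatchNorm1d(Module):
    """Batch normalization over the batch axis with running statistics.

    Training mode normalizes by batch statistics and updates exponential
    running averages; eval mode uses the running averages, which keeps
    generation deterministic and independent of batch composition.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) / ad.sqrt(var + self.eps)
        return xhat * self.gamma + self.beta


class MLP(Module):
    """Fully connected stack: ReLU hidden layers (optionally batch-normed).

    ``out_activation`` is ``"relu"`` (nonnegative outputs, He init) or
    ``"linear"`` (Xavier init, e.g. the critic score head).
    """

    def __init__(
        self,
        fan_in: int,
        hidden: tuple[int, ...],
        fan_out: int,
        rng: np.random.Generator,
        batch_norm: bool = True,
        out_activation: str = "linear",
    ):
        self.layers: list[Module] = []
        d = fan_in
        for h in hidden:
            self.layers.append(Linear(d, h, rng, init="he"))
            if batch_norm:
                self.layers.append(BatchNorm1d(h))
            d = h
        out_init = "he" if out_activation == "relu" else "xavier"
        self.out = Linear(d, fan_out, rng, init=out_init)
        if out_activation == "relu":
            # small positive bias so freshly initialized generators emit
            # strictly positive cells (the LSN layer refuses all-zero rows)
            self.out.bias.data[:] = 0.1
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
            if isinstance(layer, Linear):
                x = ad.relu(x)
        x = self.out(x)
        if self.out_activation == "relu":
            x = ad.relu(x)
        return x


class LsnLayer(Module):
    """Library-size normalization: scale each cell to a fixed total count.

    Rows with (near-)zero total raise rather than silently renormalizing --
    during GAN training this signals a dead generator.
    """

    def __init__(self, target_library: float = 20_000.0, zero_guard: float = 1e-12):
        if target_library <= 0:
            raise ValueError("target_library must be positive")
        self.target = float(target_library)
        self.zero_guard = zero_guard

    def __call__(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        """Return the normalized batch and the per-cell scaling factors."""
        if np.any(x.data < 0):
            raise ValueError("LSN input must be nonnegative")
        sums = x.sum(axis=1, keepdims=True)
        if np.any(sums.data < self.zero_guard):
            raise ValueError("LSN received a cell with (near-)zero total count")
        scale = self.target / sums
        return x * scale, scale.data.ravel().copy()


def lsn_forward(x, target: float) -> np.ndarray:
    """Array-level LSN used outside of training graphs."""
    x = np.asarray(x, dtype=np.float64)
    out, _ = LsnLayer(target)(Tensor(x))
    return out.data
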