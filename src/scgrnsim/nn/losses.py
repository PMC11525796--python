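"""Wasserstein losses, gradient penalty, and the labeler auxiliary loss."""

from __future__ import annotations

from typing import Callable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def wasserstein_losses(critic_real: Tensor, critic_fake: Tensor) -> tuple[Tensor, Tensor]:
    """Critic and generator losses of the WGAN objective.

    The critic maximizes ``mean(real) - mean(fake)``; we return its negation
    (to be *minimized*, with the gradient penalty added by the caller).  The
    generator's adversarial loss is ``-mean(fake)``: raising the critic score
    of generated samples lowers it.
    """
    if critic_real.data.size == 0 or critic_fake.data.size == 0:
        raise ValueError("empty critic score vector")
    critic_loss = critic_fake.mean() - critic_real.mean()
    gen_loss = -critic_fake.mean()
    return critic_loss, gen_loss


def gradient_penalty(
    critic: Callable[[Tensor], Tensor],
    real_batch: Tensor,
    fake_batch: Tensor,
    lam: float = 10.0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """One-sided WGAN-GP penalty on random interpolates.

    ``lam * mean((||grad_xhat critic(xhat)||_2 - 1)^2)`` with
    ``xhat = eps*x_real + (1-eps)*x_fake``, ``eps ~ U(0,1)`` per sample.  The
    inner gradient is kept in the autodiff graph so the penalty can be
    differentiated w.r.t. the critic weights.
    """
    if real_batch.shape != fake_batch.shape:
        raise ValueError(
            f"shape mismatch: real {real_batch.shape} vs fake {fake_batch.shape}"
        )
    rng = rng or np.random.default_rng()
    eps = rng.uniform(0.0, 1.0, size=(real_batch.shape[0], 1))
    xhat = Tensor(
        eps * real_batch.data + (1.0 - eps) * fake_batch.data, requires_grad=True
    )
    score = critic(xhat).sum()
    (g,) = ad.grad(score, [xhat])
    gnorm = ad.sqrt((g**2).sum(axis=1) + 1e-12)
    return lam * ((gnorm - 1.0) ** 2).mean()


def labeler_loss(estimates: Tensor, targets: Tensor) -> Tensor:
    """Batch-mean squared L2 norm between TF estimates and their true values."""
    if estimates.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: {estimates.shape} vs {targets.shape}"
        )
    n = estimates.shape[0]
    return ((estimates - targets) ** 2).sum() * (1.0 / n)
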