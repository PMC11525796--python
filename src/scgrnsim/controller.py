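"""Stage 1: pre-train a WGAN-GP over all features, then freeze its generator.

The frozen generator (the "causal controller") later supplies *raw*, pre-LSN
TF expression values to the per-gene target generators; its target-gene
outputs are discarded.  Training uses library-size-normalized reference data,
an LSN layer on the generator output, five critic updates per generator
update, the AMSGrad optimizer (beta1=0.5, beta2=0.9) with an exponentially
decaying learning rate, He/Xavier initialization, and batch normalization in
the generator but never in the critic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from .expression import ExpressionMatrix
from .nn import Tensor


@dataclass(frozen=True)
class ControllerConfig:
    noise_dim: int = 128
    hidden_layers: tuple[int, int, int] | None = None   # None -> max(256, 2*features)
    critic_layers: tuple[int, int, int] | None = None
    steps: int = 1000              # generator updates
    batch_size: int = 64
    n_critic: int = 5
    lr: float = 1e-3
    lr_decay: float = 0.99
    decay_every: int = 1000
    gp_lambda: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")
        if self.n_critic < 1 or self.steps < 1 or self.batch_size < 1:
            raise ValueError("steps, batch_size and n_critic must be positive")


def _auto_widths(widths: tuple[int, ...] | None, n_features: int) -> tuple[int, ...]:
    if widths is not None:
        return tuple(widths)
    w = max(256, 2 * n_features)
    return (w, w, w)


def make_critic(n_features: int, widths: tuple[int, ...], rng) -> nn.MLP:
    # no batch norm: it would couple per-sample gradients and defeat the
    # per-input gradient penalty
    return nn.MLP(n_features, widths, 1, rng, batch_norm=False,
                  out_activation="linear")


@dataclass
class FrozenController:
    """Trained stage-1 generator with immutable weights.

    ``sample_raw`` returns the raw (pre-LSN) generator output; ``sample_tfs``
    keeps only the TF columns (target-gene outputs are discarded) along with
    the driving noise so a batch can be replayed exactly.
    """

    generator: nn.MLP
    feature_ids: list[str]
    is_tf: np.ndarray
    noise_dim: int
    library_size: float

    def __post_init__(self):
        self.generator.eval()
        self._tf_idx = np.where(self.is_tf)[0]

    @property
    def tf_names(self) -> list[str]:
        return [self.feature_ids[i] for i in self._tf_idx]

    @property
    def tf_indices(self) -> np.ndarray:
        return self._tf_idx.copy()

    def forward_raw(self, noise: np.ndarray) -> np.ndarray:
        return self.generator(Tensor(noise)).data

    def sample_raw(self, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
        if n <= 0:
            raise ValueError("n must be positive")
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(size=(n, self.noise_dim))
        return self.forward_raw(noise), noise

    def sample_tfs(self, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
        raw, noise = self.sample_raw(n, seed)
        return raw[:, self._tf_idx], noise


def pretrain(
    train: ExpressionMatrix,
    cfg: ControllerConfig,
    history_every: int = 50,
) -> tuple[FrozenController, dict]:
    """Train the stage-1 WGAN-GP and return the frozen controller + history."""
    if train.library_size is None:
        raise ValueError(
            "training data must be library-normalized (library_size unset)"
        )
    rng = np.random.default_rng(cfg.seed)
    n_features = train.n_features
    gen = nn.MLP(
        cfg.noise_dim,
        _auto_widths(cfg.hidden_layers, n_features),
        n_features,
        rng,
        batch_norm=True,
        out_activation="relu",   # LSN requires nonnegative inputs
    )
    critic = make_critic(n_features, _auto_widths(cfg.critic_layers, n_features), rng)
    lsn = nn.LsnLayer(train.library_size)

    opt_g = nn.AMSGrad(gen.parameters(), lr=cfg.lr, lr_decay=cfg.lr_decay,
                       decay_every=cfg.decay_every)
    opt_c = nn.AMSGrad(critic.parameters(), lr=cfg.lr, lr_decay=cfg.lr_decay,
                       decay_every=cfg.decay_every)

    x = train.values
    history = {"step": [], "critic_loss": [], "gen_loss": [], "wasserstein": []}
    counters = {"critic_updates": 0, "generator_updates": 0}

    def fake_batch() -> Tensor:
        noise = rng.standard_normal(size=(cfg.batch_size, cfg.noise_dim))
        out = gen(Tensor(noise))
        normalized, _ = lsn(out)
        return normalized

    for step in range(cfg.steps):
        closs_val = w_est = 0.0
        for _ in range(cfg.n_critic):
            idx = rng.integers(0, x.shape[0], size=cfg.batch_size)
            real = Tensor(x[idx])
            fake = fake_batch()
            c_real = critic(real)
            c_fake = critic(fake.detach())
            closs, _ = nn.wasserstein_losses(c_real, c_fake)
            gp = nn.gradient_penalty(critic, real, fake.detach(),
                                     lam=cfg.gp_lambda, rng=rng)
            total = closs + gp
            nn.backward(total, critic.parameters())
            opt_c.step()
            opt_c.zero_grad()
            counters["critic_updates"] += 1
            closs_val = total.item()
            w_est = -closs.item()
        fake = fake_batch()
        gloss = -critic(fake).mean()
        nn.backward(gloss, gen.parameters())
        opt_g.step()
        opt_g.zero_grad()
        counters["generator_updates"] += 1
        if step % history_every == 0 or step == cfg.steps - 1:
            history["step"].append(step)
            history["critic_loss"].append(closs_val)
            history["gen_loss"].append(gloss.item())
            history["wasserstein"].append(w_est)

    history["counters"] = counters
    opt_g.zero_grad()
    opt_c.zero_grad()
    gen.eval()
    ctrl = FrozenController(
        generator=gen,
        feature_ids=list(train.feature_ids),
        is_tf=train.is_tf.copy(),
        noise_dim=cfg.noise_dim,
        library_size=float(train.library_size),
    )
    return ctrl, history
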