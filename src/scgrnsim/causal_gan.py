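"""Stage 2: masked per-gene target generators, critic, labeler/anti-labeler.

Every target gene gets its own generator that sees only one noise variable
and the raw (pre-LSN) expressions of its regulating TFs, as supplied by the
frozen causal controller.  All per-gene generators are realized as one large
sparse network whose weights and gradients are masked to follow the causal
graph, so genes remain mutually independent given the TFs.  Generated TF and
gene values are re-assembled in the reference feature order, passed through
the LSN layer, and judged by a critic; a labeler (trained on generated and
real cells) and an anti-labeler (generated only) regress TF values from gene
expressions alone, and their losses are added to the generator objective so
the generators cannot ignore their TF inputs.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .controller import FrozenController, make_critic, _auto_widths
from .expression import ExpressionMatrix
from .grn import RegulatoryGraph
from .nn import Tensor

DENSE_EDGE_THRESHOLD = 5000  # above this: depth 2, width multiplier 1


@dataclass(frozen=True)
class GanConfig:
    steps: int = 1000              # generator updates
    batch_size: int = 64
    n_critic: int = 5
    lr: float = 1e-3
    lr_decay: float = 0.99
    decay_every: int = 1000
    gp_lambda: float = 10.0
    labeler_weight: float = 1.0
    antilabeler_weight: float = 1.0
    labeler_width: int = 2000
    labeler_depth: int = 3
    use_labelers: bool = True      # ablation hook
    noise_per_gene: int = 1
    critic_layers: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_per_gene < 1:
            raise ValueError("noise_per_gene must be >= 1")
        if min(self.steps, self.batch_size, self.n_critic) < 1:
            raise ValueError("steps, batch_size, n_critic must be positive")


class TargetGeneratorNet(nn.Module):
    """All per-gene generators as one block-sparse masked network.

    Input layout: ``[TF values (n_tfs) | per-gene noise (n_genes * npg)]``.
    Gene *j*'s hidden block connects only to its parent TFs and its own noise
    slot(s); hidden-to-hidden and hidden-to-output connections are block
    diagonal.  Hidden width per gene is ``2 * (|parents| + npg)`` at depth 3;
    for dense graphs (> 5000 edges) depth 2 with width multiplier 1.
    """

    def __init__(
        self,
        grn: RegulatoryGraph,
        tf_order: Sequence[str],
        rng: np.random.Generator,
        noise_per_gene: int = 1,
    ):
        missing = set(grn.tfs) - set(tf_order)
        if missing:
            raise ValueError(
                "GRN TFs not supplied by the controller: "
                + ", ".join(sorted(missing)[:5])
            )
        self.grn = grn
        self.tf_order = list(tf_order)
        self.gene_order = list(grn.genes)
        self.noise_per_gene = int(noise_per_gene)
        npg = self.noise_per_gene

        tf_pos = {t: i for i, t in enumerate(self.tf_order)}
        pm = grn.parent_map()
        self.parent_indices = [
            np.array([tf_pos[t] for t in pm[g]]) for g in self.gene_order
        ]
        if any(len(p) == 0 for p in self.parent_indices):
            raise ValueError("every gene needs at least one parent TF")

        dense = grn.n_edges > DENSE_EDGE_THRESHOLD
        self.depth = 2 if dense else 3
        mult = 1 if dense else 2
        n_tfs, n_genes = len(self.tf_order), len(self.gene_order)
        in_dim = n_tfs + n_genes * npg
        widths = [mult * (len(p) + npg) for p in self.parent_indices]
        offsets = np.concatenate([[0], np.cumsum(widths)]).astype(int)
        hidden = int(offsets[-1])
        self.hidden_widths = widths

        mask_in = np.zeros((in_dim, hidden))
        mask_block = np.zeros((hidden, hidden))
        mask_out = np.zeros((hidden, n_genes))
        for j, parents in enumerate(self.parent_indices):
            lo, hi = offsets[j], offsets[j + 1]
            mask_in[parents, lo:hi] = 1.0
            mask_in[n_tfs + j * npg : n_tfs + (j + 1) * npg, lo:hi] = 1.0
            mask_block[lo:hi, lo:hi] = 1.0
            mask_out[lo:hi, j] = 1.0

        self.layers: list[nn.Module] = [nn.MaskedLinear(mask_in, rng),
                                        nn.BatchNorm1d(hidden)]
        for _ in range(self.depth - 1):
            self.layers.append(nn.MaskedLinear(mask_block.copy(), rng))
            self.layers.append(nn.BatchNorm1d(hidden))
        self.out = nn.MaskedLinear(mask_out, rng)
        self.out.bias.data[:] = 0.1  # fresh generators emit positive cells

    def __call__(self, tf_values: Tensor, noise: Tensor) -> Tensor:
        x = nn.concat([tf_values, noise], axis=1)
        for layer in self.layers:
            x = layer(x)
            if isinstance(layer, nn.MaskedLinear):
                x = nn.relu(x)
        return nn.relu(self.out(x))


def build_target_generators(
    grn: RegulatoryGraph,
    tf_order: Sequence[str],
    seed: int = 0,
    noise_per_gene: int = 1,
) -> TargetGeneratorNet:
    return TargetGeneratorNet(
        grn, tf_order, np.random.default_rng(seed), noise_per_gene
    )


def make_labeler(
    n_genes: int, n_tfs: int, width: int, depth: int, rng
) -> nn.MLP:
    return nn.MLP(n_genes, (width,) * depth, n_tfs, rng, batch_norm=True,
                  out_activation="linear")


@dataclass
class GanBundle:
    """The trained artifact: all components plus the settings that made them."""

    controller: FrozenController
    target_net: TargetGeneratorNet
    critic: nn.MLP
    labeler: nn.MLP | None
    anti_labeler: nn.MLP | None
    grn: RegulatoryGraph
    feature_ids: list[str]
    is_tf: np.ndarray
    library_size: float
    config: GanConfig
    history: dict = field(default_factory=dict)

    def __post_init__(self):
        # column permutation taking [controller TFs | net genes] -> data order
        concat_pos = {t: i for i, t in enumerate(self.controller.tf_names)}
        n_tfs = len(self.controller.tf_names)
        for j, g in enumerate(self.target_net.gene_order):
            concat_pos[g] = n_tfs + j
        try:
            self._perm = np.array([concat_pos[f] for f in self.feature_ids])
        except KeyError as e:  # pragma: no cover
            raise ValueError(f"feature {e} not produced by any component")

    @property
    def feature_hash(self) -> str:
        import hashlib

        return hashlib.sha256("\t".join(self.feature_ids).encode()).hexdigest()[:16]

    def eval(self) -> None:
        for m in (self.target_net, self.critic, self.labeler, self.anti_labeler):
            if m is not None:
                m.eval()

    def forward_genes(self, tf_values: np.ndarray, gene_noise: np.ndarray) -> np.ndarray:
        """Target-generator forward on arrays (no graph)."""
        return self.target_net(Tensor(tf_values), Tensor(gene_noise)).data

    def assemble(self, tf_values: np.ndarray, gene_values: np.ndarray) -> np.ndarray:
        """Arrange [TFs | genes] into the reference feature order."""
        return np.concatenate([tf_values, gene_values], axis=1)[:, self._perm]

    def save(self, path: str | Path) -> None:
        # gradients hold closures over the training graph; drop them
        for m in (self.controller.generator, self.target_net, self.critic,
                  self.labeler, self.anti_labeler):
            if m is not None:
                for p in m.parameters():
                    p.grad = None
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @staticmethod
    def load(path: str | Path) -> "GanBundle":
        with open(path, "rb") as f:
            return pickle.load(f)


def train(
    train_data: ExpressionMatrix,
    ctrl: FrozenController,
    grn: RegulatoryGraph,
    cfg: GanConfig,
    history_every: int = 50,
) -> GanBundle:
    """Adversarial + auxiliary training of the target generators.

    Per generator update: five critic updates (Wasserstein loss + gradient
    penalty), one labeler update (generated and real gene->TF pairs, losses
    summed), one anti-labeler update (generated only), then one generator
    update minimizing ``adversarial + labeler + anti-labeler`` losses.  The
    labeler/anti-labeler losses are minimized from the start of training.
    """
    missing = (set(grn.tfs) | set(grn.genes)) - set(train_data.feature_ids)
    if missing:
        raise ValueError(
            "GRN features absent from the data: " + ", ".join(sorted(missing)[:10])
        )
    if train_data.library_size is None:
        raise ValueError("training data must be library-normalized")
    if train_data.feature_ids != ctrl.feature_ids:
        raise ValueError("controller and training data feature orders differ")

    rng = np.random.default_rng(cfg.seed)
    n_features = train_data.n_features
    npg = cfg.noise_per_gene

    target_net = TargetGeneratorNet(grn, ctrl.tf_names, rng, npg)
    critic = make_critic(n_features, _auto_widths(cfg.critic_layers, n_features), rng)
    n_genes, n_tfs = len(target_net.gene_order), len(ctrl.tf_names)
    if cfg.use_labelers:
        labeler = make_labeler(n_genes, n_tfs, cfg.labeler_width,
                               cfg.labeler_depth, rng)
        anti = make_labeler(n_genes, n_tfs, cfg.labeler_width,
                            cfg.labeler_depth, rng)
    else:
        labeler = anti = None

    lsn = nn.LsnLayer(train_data.library_size)
    bundle = GanBundle(
        controller=ctrl, target_net=target_net, critic=critic, labeler=labeler,
        anti_labeler=anti, grn=grn, feature_ids=list(train_data.feature_ids),
        is_tf=train_data.is_tf.copy(), library_size=float(train_data.library_size),
        config=cfg,
    )
    perm = bundle._perm

    opt_kw = dict(lr=cfg.lr, lr_decay=cfg.lr_decay, decay_every=cfg.decay_every)
    opt_g = nn.AMSGrad(target_net.parameters(), **opt_kw)
    opt_c = nn.AMSGrad(critic.parameters(), **opt_kw)
    if cfg.use_labelers:
        opt_l = nn.AMSGrad(labeler.parameters(), **opt_kw)
        opt_a = nn.AMSGrad(anti.parameters(), **opt_kw)

    x = train_data.values
    gene_cols = np.array(
        [train_data.feature_ids.index(g) for g in target_net.gene_order]
    )
    tf_cols = np.array(
        [train_data.feature_ids.index(t) for t in ctrl.tf_names]
    )

    def forward_fake():
        """Full stage-2 forward with graph; returns (normalized, genes, tf_raw)."""
        noise_c = rng.standard_normal(size=(cfg.batch_size, ctrl.noise_dim))
        tf_raw = ctrl.forward_raw(noise_c)[:, ctrl.tf_indices]  # frozen: arrays
        gnoise = rng.standard_normal(size=(cfg.batch_size, n_genes * npg))
        genes = target_net(Tensor(tf_raw), Tensor(gnoise))
        full = nn.take_columns(nn.concat([Tensor(tf_raw), genes], axis=1), perm)
        normalized, _ = lsn(full)
        return normalized, genes, tf_raw

    history = {"step": [], "critic_loss": [], "gen_loss": [], "wasserstein": [],
               "labeler_loss": [], "antilabeler_loss": []}
    counters = {"critic_updates": 0, "generator_updates": 0}

    for step in range(cfg.steps):
        closs_val = w_est = 0.0
        for _ in range(cfg.n_critic):
            idx = rng.integers(0, x.shape[0], size=cfg.batch_size)
            real = Tensor(x[idx])
            fake, _, _ = forward_fake()
            fake = fake.detach()
            closs, _ = nn.wasserstein_losses(critic(real), critic(fake))
            gp = nn.gradient_penalty(critic, real, fake, lam=cfg.gp_lambda, rng=rng)
            total = closs + gp
            nn.backward(total, critic.parameters())
            opt_c.step()
            opt_c.zero_grad()
            counters["critic_updates"] += 1
            closs_val, w_est = total.item(), -closs.item()

        lab_val = anti_val = 0.0
        if cfg.use_labelers:
            # labeler: generated and real (gene -> TF) pairs, losses summed;
            # both sides see library-normalized gene expressions
            fake, genes, tf_raw = forward_fake()
            genes_d = Tensor(fake.data[:, gene_cols])
            est_gen = labeler(genes_d)
            idx = rng.integers(0, x.shape[0], size=cfg.batch_size)
            est_real = labeler(Tensor(x[idx][:, gene_cols]))
            lloss = nn.labeler_loss(est_gen, Tensor(tf_raw)) + nn.labeler_loss(
                est_real, Tensor(x[idx][:, tf_cols])
            )
            nn.backward(lloss, labeler.parameters())
            opt_l.step()
            opt_l.zero_grad()
            # anti-labeler: generated only
            est_anti = anti(genes_d)
            aloss = nn.labeler_loss(est_anti, Tensor(tf_raw))
            nn.backward(aloss, anti.parameters())
            opt_a.step()
            opt_a.zero_grad()
            lab_val, anti_val = lloss.item(), aloss.item()

        # generator update
        fake, genes, tf_raw = forward_fake()
        gloss = -critic(fake).mean()
        if cfg.use_labelers:
            genes_norm = nn.take_columns(fake, gene_cols)
            gloss = gloss + cfg.labeler_weight * nn.labeler_loss(
                labeler(genes_norm), Tensor(tf_raw)
            )
            gloss = gloss + cfg.antilabeler_weight * nn.labeler_loss(
                anti(genes_norm), Tensor(tf_raw)
            )
        nn.backward(gloss, target_net.parameters())
        opt_g.step()
        opt_g.zero_grad()
        counters["generator_updates"] += 1

        if step % history_every == 0 or step == cfg.steps - 1:
            history["step"].append(step)
            history["critic_loss"].append(closs_val)
            history["gen_loss"].append(gloss.item())
            history["wasserstein"].append(w_est)
            history["labeler_loss"].append(lab_val)
            history["antilabeler_loss"].append(anti_val)

    history["counters"] = counters
    bundle.history = history
    opt_g.zero_grad()
    opt_c.zero_grad()
    if cfg.use_labelers:
        opt_l.zero_grad()
        opt_a.zero_grad()
    bundle.eval()
    return bundle
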