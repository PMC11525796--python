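"""Synthetic reference data from a known structural causal model (SCM).

The generator emulates the statistical structure a GRN-guided simulator
assumes about scRNA-seq data: heavy-tailed positive TF expression (lognormal),
target genes that are nonlinear combinatorial functions of their regulating
TFs plus independent biological noise, a multiplicative per-cell library-size
factor, and Bernoulli dropout as technical noise.  Because the fixture is an
explicit SCM rather than a trained model, interventions (TF knockouts) have
exact ground truth: zeroing a TF before evaluating the structural equations
changes descendants and nothing else.

Counts are left continuous by default (downstream training operates on
library-normalized values); pass ``integerize=True`` for a Poisson layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .expression import ExpressionMatrix
from .grn import RegulatoryGraph, random_grn

_FAMILIES = ("linear", "hill", "interaction")


@dataclass(frozen=True)
class SyntheticConfig:
    n_cells: int = 2000
    n_genes: int = 30
    n_tfs: int = 10
    k_parents: int = 3
    regulation: str = "hill"
    noise_sd: float = 0.1        # biological noise, relative to each gene's scale
    dropout_rate: float = 0.2    # Bernoulli technical dropout
    library_shape: tuple[float, float] = (0.0, 0.25)  # lognormal (mu, sigma)
    seed: int = 0

    def __post_init__(self):
        if self.k_parents > self.n_tfs:
            raise ValueError("k_parents must be <= n_tfs")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.regulation not in _FAMILIES:
            raise ValueError(f"regulation must be one of {_FAMILIES}")
        if min(self.n_cells, self.n_genes, self.n_tfs) < 1:
            raise ValueError("n_cells, n_genes, n_tfs must be positive")


def _tf_names(n: int) -> list[str]:
    return [f"TF{i + 1:03d}" for i in range(n)]


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


@dataclass
class _Mechanism:
    """Frozen structural equation of one gene."""

    parents: np.ndarray           # TF column indices
    weights: np.ndarray           # positive regulation strengths
    signs: np.ndarray             # +1 activation / -1 repression (hill only)
    half_sat: np.ndarray          # hill half-saturation constants
    pairs: np.ndarray             # index pairs (into parents) for interactions
    pair_weights: np.ndarray
    scale: float                  # overall gene expression scale
    family: str

    def evaluate(self, tf_values: np.ndarray) -> np.ndarray:
        t = tf_values[:, self.parents]
        if self.family == "linear":
            base = t @ self.weights
        else:
            h = 2.0
            act = t**h / (self.half_sat[None, :] ** h + t**h)
            act = np.where(self.signs[None, :] > 0, act, 1.0 - act)
            base = act @ self.weights
            if self.family == "interaction" and len(self.pairs):
                prod = act[:, self.pairs[:, 0]] * act[:, self.pairs[:, 1]]
                base = base + prod @ self.pair_weights
        return self.scale * base


def _simulate(
    cfg: SyntheticConfig,
    tf_transform: Callable[[np.ndarray], np.ndarray] | None = None,
    integerize: bool = False,
) -> tuple[ExpressionMatrix, RegulatoryGraph]:
    """Shared sampling core.  All randomness is drawn *before* the optional
    TF intervention, so matrices generated under the same config differ only
    through the causal consequences of the intervention."""
    rng = np.random.default_rng(cfg.seed)
    tfs, genes = _tf_names(cfg.n_tfs), _gene_names(cfg.n_genes)
    graph = random_grn(genes, tfs, cfg.k_parents, seed=cfg.seed + 1)
    tf_index = {tf: i for i, tf in enumerate(tfs)}

    tf_mu = rng.uniform(np.log(1.0), np.log(5.0), size=cfg.n_tfs)
    tf_values = rng.lognormal(
        mean=tf_mu[None, :], sigma=0.6, size=(cfg.n_cells, cfg.n_tfs)
    )
    tf_medians = np.exp(tf_mu)  # population medians, independent of the sample

    mechanisms = []
    for gene in graph.genes:
        parents = np.array([tf_index[tf] for tf in graph.parents(gene)])
        k = len(parents)
        weights = rng.uniform(0.5, 1.5, size=k)
        signs = np.where(rng.random(k) < 0.7, 1.0, -1.0)
        half_sat = tf_medians[parents] * rng.uniform(0.5, 2.0, size=k)
        if cfg.regulation == "interaction" and k >= 2:
            n_pairs = min(k, 3)
            pairs = np.array(
                [sorted(rng.choice(k, size=2, replace=False)) for _ in range(n_pairs)]
            )
            pair_weights = rng.uniform(0.5, 1.5, size=n_pairs)
        else:
            pairs = np.empty((0, 2), dtype=int)
            pair_weights = np.empty(0)
        scale = float(rng.lognormal(np.log(5.0), 0.5))
        mechanisms.append(
            _Mechanism(parents, weights, signs, half_sat, pairs, pair_weights,
                       scale, cfg.regulation)
        )

    gene_noise = rng.standard_normal(size=(cfg.n_cells, cfg.n_genes))
    library = rng.lognormal(
        cfg.library_shape[0], cfg.library_shape[1], size=cfg.n_cells
    )
    dropout_u = rng.random(size=(cfg.n_cells, cfg.n_tfs + cfg.n_genes))

    if tf_transform is not None:
        tf_values = tf_transform(tf_values.copy())

    gene_values = np.empty((cfg.n_cells, cfg.n_genes))
    for j, mech in enumerate(mechanisms):
        f = mech.evaluate(tf_values)
        gene_values[:, j] = f + cfg.noise_sd * mech.scale * gene_noise[:, j]
    gene_values = np.maximum(gene_values, 0.0)

    values = np.concatenate([tf_values, gene_values], axis=1)
    values *= library[:, None]
    if cfg.dropout_rate > 0:
        values = np.where(dropout_u < cfg.dropout_rate, 0.0, values)
    if integerize:
        values = np.random.default_rng(cfg.seed + 2).poisson(values).astype(float)

    em = ExpressionMatrix(
        values,
        cell_ids=[f"cell{i:05d}" for i in range(cfg.n_cells)],
        feature_ids=tfs + genes,
        is_tf=np.array([True] * cfg.n_tfs + [False] * cfg.n_genes),
    )
    return em, graph


def simulate_reference(
    cfg: SyntheticConfig,
    knockout: Iterable[str] | None = None,
    integerize: bool = False,
) -> tuple[ExpressionMatrix, RegulatoryGraph]:
    """Sample a reference dataset and return it with its generating graph.

    ``knockout`` names TFs to zero *before* the structural equations are
    evaluated, yielding the exact interventional counterpart of the
    observational dataset under the same seed.
    """
    transform = None
    if knockout:
        ko = list(knockout)
        unknown = set(ko) - set(_tf_names(cfg.n_tfs))
        if unknown:
            raise KeyError(f"unknown TF(s) in knockout: {sorted(unknown)}")
        idx = [int(t[2:]) - 1 for t in ko]

        def transform(t: np.ndarray) -> np.ndarray:
            t[:, idx] = 0.0
            return t

    return _simulate(cfg, tf_transform=transform, integerize=integerize)


def simulate_two_states(
    cfg: SyntheticConfig, shift: float, n_markers: int = 2
) -> tuple[ExpressionMatrix, np.ndarray, list[str], RegulatoryGraph]:
    """Two subpopulations whose marker TFs differ in mean by ``shift``.

    Cells are split half/half; state-1 cells have ``shift`` added to their
    marker TF expression before the gene equations are evaluated, so the
    difference propagates causally to downstream genes.  Returns
    (matrix, state labels, marker TF names, graph).  With ``shift == 0`` the
    two states are exchangeable.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    labels = np.zeros(cfg.n_cells, dtype=int)
    labels[cfg.n_cells // 2 :] = 1
    markers = _tf_names(cfg.n_tfs)[:n_markers]
    midx = [int(t[2:]) - 1 for t in markers]

    em0, graph = _simulate(cfg)
    if shift == 0:
        return em0, labels, markers, graph

    def transform(t: np.ndarray) -> np.ndarray:
        t[:, midx] += shift
        return t

    em1, _ = _simulate(cfg, tf_transform=transform)
    values = em0.values.copy()
    values[labels == 1] = em1.values[labels == 1]
    em = ExpressionMatrix(values, em0.cell_ids, em0.feature_ids, em0.is_tf)
    return em, labels, markers, graph
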