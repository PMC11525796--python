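"""Sampling, deterministic replay, in-silico TF knockout, and the matched
case/control differential test.

Generation saves everything a forward pass consumed -- controller noise,
per-gene generator noise, the controller's raw TF expression matrix, and the
per-cell LSN scaling factors -- so subsequent passes can replay exactly the
same batch of cells.  A knockout zeroes named TFs in the *saved* TF matrix
and re-runs only the target generators with the saved noises and saved LSN
scales, yielding matched case/control cells: genes not downstream of a
knocked-out TF are bit-identical between the two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .causal_gan import GanBundle
from .expression import ExpressionMatrix
from .grn import RegulatoryGraph


@dataclass
class SimulationBatch:
    """Deterministic replay bundle for one generated batch of cells."""

    controller_noise: np.ndarray   # n x noise_dim
    gene_noise: np.ndarray         # n x (n_genes * noise_per_gene)
    tf_matrix: np.ndarray          # n x n_tfs, raw (pre-LSN) controller TFs
    lsn_scale: np.ndarray          # per-cell scaling factors
    expression: ExpressionMatrix   # the resulting (post-LSN) cells
    feature_hash: str

    @property
    def n_cells(self) -> int:
        return self.tf_matrix.shape[0]


def _forward(model: GanBundle, tf_matrix: np.ndarray,
             gene_noise: np.ndarray) -> np.ndarray:
    """Target-generator pass + assembly, returning the raw full matrix."""
    model.eval()
    genes = model.forward_genes(tf_matrix, gene_noise)
    return model.assemble(tf_matrix, genes)


def generate(model: GanBundle, n: int, seed: int) -> SimulationBatch:
    """Sample ``n`` cells and capture the replay bundle."""
    if n <= 0:
        raise ValueError("n must be positive")
    model.eval()
    ctrl = model.controller
    rng = np.random.default_rng(seed)
    controller_noise = rng.standard_normal(size=(n, ctrl.noise_dim))
    tf_matrix = ctrl.forward_raw(controller_noise)[:, ctrl.tf_indices]
    npg = model.config.noise_per_gene
    gene_noise = rng.standard_normal(
        size=(n, len(model.target_net.gene_order) * npg)
    )
    raw = _forward(model, tf_matrix, gene_noise)
    sums = raw.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("generated cell with zero total count")
    scale = model.library_size / sums
    values = raw * scale[:, None]
    expression = ExpressionMatrix(
        values,
        cell_ids=[f"sim{i:05d}" for i in range(n)],
        feature_ids=list(model.feature_ids),
        is_tf=model.is_tf.copy(),
        library_size=model.library_size,
    )
    return SimulationBatch(
        controller_noise=controller_noise,
        gene_noise=gene_noise,
        tf_matrix=tf_matrix,
        lsn_scale=scale,
        expression=expression,
        feature_hash=model.feature_hash,
    )


def _check_batch(model: GanBundle, batch: SimulationBatch) -> None:
    if batch.feature_hash != model.feature_hash:
        raise ValueError(
            "batch was produced by a model with a different feature set"
        )


def replay(model: GanBundle, batch: SimulationBatch) -> ExpressionMatrix:
    """Re-run the saved batch; bit-identical to ``batch.expression``."""
    _check_batch(model, batch)
    raw = _forward(model, batch.tf_matrix, batch.gene_noise)
    values = raw * batch.lsn_scale[:, None]
    return ExpressionMatrix(
        values,
        cell_ids=list(batch.expression.cell_ids),
        feature_ids=list(model.feature_ids),
        is_tf=model.is_tf.copy(),
    )


def knockout(
    model: GanBundle, batch: SimulationBatch, tfs_to_zero: Iterable[str]
) -> ExpressionMatrix:
    """Zero the named TFs in the saved TF matrix and re-run the generators.

    Saved noises and saved per-cell LSN scaling factors are reused, so the
    result is the matched interventional counterpart of ``batch.expression``.
    An empty TF set returns the control batch unchanged.
    """
    _check_batch(model, batch)
    tfs_to_zero = list(tfs_to_zero)
    tf_names = model.controller.tf_names
    unknown = set(tfs_to_zero) - set(tf_names)
    if unknown:
        raise KeyError(f"unknown TF(s): {sorted(unknown)}")
    tfm = batch.tf_matrix.copy()
    pos = [tf_names.index(t) for t in tfs_to_zero]
    tfm[:, pos] = 0.0
    raw = _forward(model, tfm, batch.gene_noise)
    values = raw * batch.lsn_scale[:, None]
    return ExpressionMatrix(
        values,
        cell_ids=list(batch.expression.cell_ids),
        feature_ids=list(model.feature_ids),
        is_tf=model.is_tf.copy(),
    )


def _paired_wilcoxon(control: np.ndarray, case: np.ndarray) -> float:
    """Two-sided signed-rank p-value; all-zero differences give p = 1."""
    diffs = case - control
    if np.all(diffs == 0):
        return 1.0
    res = stats.wilcoxon(case, control, zero_method="wilcox",
                         alternative="two-sided")
    return float(res.pvalue)


def edge_de_test(
    control: ExpressionMatrix,
    case: ExpressionMatrix,
    grn: RegulatoryGraph,
    knocked_tf: str,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-edge paired differential test for one knocked-out TF.

    For every child gene of ``knocked_tf``, a two-sided Wilcoxon signed-rank
    test on the paired (same-cell) expressions, Benjamini-Hochberg adjusted
    across the tested edges.  Use :func:`knockout_experiment` to pool the BH
    family over several TFs.
    """
    if control.n_cells != case.n_cells:
        raise ValueError("control and case must contain the same cells")
    if knocked_tf not in grn.tfs:
        raise ValueError(f"{knocked_tf!r} is not a TF of the graph")
    rows = []
    for gene in grn.children(knocked_tf):
        p = _paired_wilcoxon(control.column(gene), case.column(gene))
        rows.append({"tf": knocked_tf, "gene": gene, "pvalue": p})
    df = pd.DataFrame(rows)
    if adjust and len(df):
        df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df


def knockout_experiment(
    model: GanBundle,
    batch: SimulationBatch,
    tfs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Knock out each TF (one at a time) and test all its GRN edges.

    BH adjustment is applied jointly across every (TF, child gene) pair
    tested in the experiment.  Returns a frame with columns
    tf / gene / pvalue / qvalue.
    """
    grn = model.grn
    tfs = list(tfs) if tfs is not None else list(grn.tfs)
    control = batch.expression
    frames = []
    for tf in tfs:
        case = knockout(model, batch, [tf])
        frames.append(edge_de_test(control, case, grn, tf, adjust=False))
    df = pd.concat(frames, ignore_index=True)
    df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df


def significant_edge_fraction(de: pd.DataFrame, alpha: float = 0.05) -> float:
    """Fraction of tested edges whose knockout changed the child (q < alpha)."""
    if not len(de):
        raise ValueError("empty differential-test table")
    return float((de["qvalue"] < alpha).mean())
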