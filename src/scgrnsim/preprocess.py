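"""Reference-data preprocessing: filters, HVG selection, normalization, splits.

The pipeline mirrors the common GAN-simulator recipe for scRNA-seq: drop
cells expressing fewer than 10 genes, drop genes expressed in fewer than 3
cells, keep the top 1000 highly variable genes by the binned-dispersion
method, and scale every cell to a library size of 20,000 counts.  Filters run
cells-then-genes, in that order.
"""

from __future__ import annotations

import numpy as np

from .expression import ExpressionMatrix


def filter_cells(m: ExpressionMatrix, min_genes: int = 10) -> ExpressionMatrix:
    """Keep cells with nonzero counts in at least ``min_genes`` features."""
    keep = (m.values > 0).sum(axis=1) >= min_genes
    if not keep.any():
        raise ValueError("all cells removed by the cell filter")
    return m.subset_cells(np.where(keep)[0])


def filter_genes(m: ExpressionMatrix, min_cells: int = 3) -> ExpressionMatrix:
    """Keep features with nonzero counts in at least ``min_cells`` cells."""
    keep = (m.values > 0).sum(axis=0) >= min_cells
    if not keep.any():
        raise ValueError("all features removed by the gene filter")
    names = [f for f, k in zip(m.feature_ids, keep) if k]
    return m.subset_features(names)


def select_hvg(
    m: ExpressionMatrix, n_top: int = 1000, n_bins: int = 20
) -> ExpressionMatrix:
    """Top ``n_top`` highly variable features by binned normalized dispersion.

    Dispersions are computed on a per-cell-normalized, log1p-transformed copy
    (the data itself is not modified): per feature, dispersion = variance /
    mean (on the de-logged scale), log-transformed and z-scored within 20
    mean-expression bins.  Features are returned ordered by dispersion rank.
    TF flags are carried over.
    """
    if n_top > m.n_features:
        raise ValueError(
            f"n_top={n_top} exceeds number of features ({m.n_features})"
        )
    import scanpy as sc

    a = m.to_anndata()
    sc.pp.normalize_total(a, target_sum=1e4)
    sc.pp.log1p(a)
    sc.pp.highly_variable_genes(
        a, n_top_genes=n_top, n_bins=n_bins, flavor="seurat"
    )
    disp = a.var["dispersions_norm"].to_numpy()
    order = np.argsort(-np.nan_to_num(disp, nan=-np.inf), kind="stable")[:n_top]
    names = [m.feature_ids[i] for i in order]
    return m.subset_features(names)


def normalize_library(
    m: ExpressionMatrix, target: float = 20_000.0
) -> ExpressionMatrix:
    """Scale each cell so its counts sum to ``target``; records library_size."""
    sums = m.values.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError(
            "cell(s) with zero total count; run the filters before normalizing"
        )
    values = m.values * (target / sums)[:, None]
    return ExpressionMatrix(
        values, list(m.cell_ids), list(m.feature_ids), m.is_tf.copy(), float(target)
    )


def split_dataset(
    m: ExpressionMatrix, test_cells: int, validation_cells: int, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Seeded disjoint (train, validation, test) partition with exact sizes."""
    if test_cells + validation_cells >= m.n_cells:
        raise ValueError(
            f"test+validation ({test_cells + validation_cells}) must be "
            f"smaller than the number of cells ({m.n_cells})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m.n_cells)
    test_idx = np.sort(perm[:test_cells])
    val_idx = np.sort(perm[test_cells : test_cells + validation_cells])
    train_idx = np.sort(perm[test_cells + validation_cells :])
    return (
        m.subset_cells(train_idx),
        m.subset_cells(val_idx),
        m.subset_cells(test_idx),
    )


def preprocess_pipeline(
    m: ExpressionMatrix,
    tf_list: list[str] | None = None,
    min_genes: int = 10,
    min_cells: int = 3,
    n_hvg: int | None = 1000,
    library_size: float = 20_000.0,
) -> ExpressionMatrix:
    """Filters -> optional HVG selection -> TF flagging -> normalization."""
    m = filter_cells(m, min_genes)
    m = filter_genes(m, min_cells)
    if n_hvg is not None and n_hvg < m.n_features:
        m = select_hvg(m, n_top=n_hvg)
    if tf_list is not None:
        m = m.with_tf_flags(tf_list)
    return normalize_library(m, library_size)
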