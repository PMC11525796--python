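"""Resemblance metrics between real and simulated cell sets.

Centroid cosine/Euclidean distances, maximum mean discrepancy (MMD) with a
sum of three Gaussian kernels and a 25-nearest-neighbor median bandwidth
rule, the (mean) integration local inverse Simpson's index (iLISI/miLISI),
and the AUROC of a random-forest real-vs-simulated classifier on the top 50
principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist, cosine as cosine_dist, euclidean

from .expression import ExpressionMatrix


def _as_array(x) -> np.ndarray:
    if isinstance(x, ExpressionMatrix):
        return x.values
    return np.asarray(x, dtype=np.float64)


def centroid_distances(X, Y) -> tuple[float, float]:
    """Cosine and Euclidean distance between the two sets' mean vectors."""
    X, Y = _as_array(X), _as_array(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensions differ")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    return float(cosine_dist(cx, cy)), float(euclidean(cx, cy))


def _mmd_bandwidth(pooled: np.ndarray, knn: int) -> float:
    """Median over points of the mean distance to their ``knn`` nearest
    neighbors (excluding self)."""
    from sklearn.neighbors import NearestNeighbors

    if pooled.shape[0] <= knn:
        raise ValueError(
            f"need more than {knn} pooled points for the {knn}-NN bandwidth "
            "rule; pass explicit sigmas instead"
        )
    nbrs = NearestNeighbors(n_neighbors=knn + 1).fit(pooled)
    dist, _ = nbrs.kneighbors(pooled)
    base = float(np.median(dist[:, 1:].mean(axis=1)))
    if base <= 0:
        raise ValueError(
            "degenerate geometry: median 25-NN distance is zero; pass "
            "explicit sigmas"
        )
    return base


def mmd(
    X,
    Y,
    knn_for_sigma: int = 25,
    sigmas: tuple[float, float, float] | None = None,
    return_settings: bool = False,
):
    """Kernel two-sample MMD (square root of the biased V-statistic).

    The kernel is a sum of three Gaussians ``exp(-d^2 / sigma_i^2)`` whose
    bandwidths are the pooled 25-NN median distance divided by factors 0.5,
    1, and 2.  The biased estimator keeps the diagonal terms, so identical
    samples give exactly zero.
    """
    X, Y = _as_array(X), _as_array(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensions differ")
    if sigmas is None:
        base = _mmd_bandwidth(np.vstack([X, Y]), knn_for_sigma)
        sigmas = (base / 0.5, base / 1.0, base / 2.0)

    def kernel(a, b):
        d2 = cdist(a, b, "sqeuclidean")
        return sum(np.exp(-d2 / s**2) for s in sigmas)

    m2 = kernel(X, X).mean() + kernel(Y, Y).mean() - 2.0 * kernel(X, Y).mean()
    value = float(np.sqrt(max(m2, 0.0)))
    if return_settings:
        return value, {"sigmas": tuple(float(s) for s in sigmas),
                       "knn_for_sigma": knn_for_sigma, "estimator": "biased"}
    return value


def lisi(
    embedding: np.ndarray,
    labels: np.ndarray,
    perplexity: int = 30,
) -> np.ndarray:
    """Per-point local inverse Simpson's index over datatypes.

    For each point, Gaussian weights over its ``3 * perplexity`` nearest
    neighbors are calibrated by binary search so their entropy matches
    ``log(perplexity)``; the label distribution under those weights gives
    the inverse Simpson index ``1 / sum_b p_b^2``, between 1 and the number
    of labels present.
    """
    from sklearn.neighbors import NearestNeighbors

    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    n = embedding.shape[0]
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        warnings.warn("single label present; all iLISI values are 1")
        return np.ones(n)
    k = min(3 * perplexity, n - 1)
    # the point itself belongs to its neighborhood: a location occupied by
    # one point of each datatype then contributes both labels with equal
    # weight, making the perfectly-mixed case evaluate to exactly 2
    nbrs = NearestNeighbors(n_neighbors=k).fit(embedding)
    dist, idx = nbrs.kneighbors(embedding)
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(64):
            w = np.exp(-beta * (d2 - d2.min()))
            wsum = w.sum()
            p = w / wsum
            h = -(p * np.log(np.maximum(p, 1e-300))).sum()
            if abs(h - target) < 1e-7:
                break
            if h > target:  # too flat -> sharpen
                lo = beta
                beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = beta / 2 if lo == 0.0 else (beta + lo) / 2
        probs = np.bincount(codes[idx[i]], weights=p, minlength=len(uniq))
        probs = probs / probs.sum()
        out[i] = 1.0 / np.sum(probs**2)
    return out


def milisi(embedding, labels, perplexity: int = 30) -> float:
    """Mean iLISI; 1 = unmixed, 2 = perfectly mixed for two datatypes."""
    return float(lisi(embedding, labels, perplexity).mean())


def rf_auroc(
    X,
    Y,
    n_pcs: int = 50,
    trees: int = 1000,
    seed: int = 0,
    n_folds: int = 5,
    return_settings: bool = False,
):
    """AUROC of a random forest distinguishing the two sets.

    PCA is fit on the pooled set (components capped at the data rank); the
    forest (Gini impurity) is evaluated by stratified cross-validated
    probabilities.  0.5 means indistinguishable.
    """
    from sklearn.decomposition import PCA
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    X, Y = _as_array(X), _as_array(Y)
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError("need at least 2 cells per class")
    pooled = np.vstack([X, Y])
    labels = np.r_[np.zeros(X.shape[0]), np.ones(Y.shape[0])]
    n_pcs_used = int(min(n_pcs, pooled.shape[1], pooled.shape[0] - 1))
    pcs = PCA(n_components=n_pcs_used, random_state=seed).fit_transform(pooled)
    clf = RandomForestClassifier(
        n_estimators=trees, criterion="gini", random_state=seed, n_jobs=1
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = cross_val_predict(clf, pcs, labels, cv=cv, method="predict_proba")
    value = float(roc_auc_score(labels, proba[:, 1]))
    if return_settings:
        return value, {"n_pcs": n_pcs_used, "trees": trees, "seed": seed,
                       "folds": n_folds}
    return value


@dataclass
class MetricReport:
    """Named resemblance metrics plus the exact settings that produced them."""

    cosine_centroid: float
    euclidean_centroid: float
    mmd: float
    milisi: float | None
    rf_auroc: float
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_resemblance(
    real: ExpressionMatrix,
    sim: ExpressionMatrix,
    embedding: np.ndarray | None = None,
    seed: int = 0,
    perplexity: int = 30,
    trees: int = 1000,
    n_pcs: int = 50,
) -> MetricReport:
    """All resemblance metrics in one report.

    ``embedding`` (cells of ``real`` then ``sim`` in a low-dimensional space)
    is required for miLISI; the caller controls how it was computed (t-SNE,
    UMAP, PCA, ...).  If omitted, miLISI is reported as None.
    """
    if real.feature_ids != sim.feature_ids:
        raise ValueError("real and simulated feature sets/orders differ")
    cos, euc = centroid_distances(real, sim)
    mmd_val, mmd_settings = mmd(real, sim, return_settings=True)
    auroc, rf_settings = rf_auroc(
        real, sim, n_pcs=n_pcs, trees=trees, seed=seed, return_settings=True
    )
    mil = None
    if embedding is not None:
        labels = np.r_[np.zeros(real.n_cells), np.ones(sim.n_cells)]
        mil = milisi(embedding, labels, perplexity)
    return MetricReport(
        cosine_centroid=cos,
        euclidean_centroid=euc,
        mmd=mmd_val,
        milisi=mil,
        rf_auroc=auroc,
        settings={"mmd": mmd_settings, "rf": rf_settings,
                  "perplexity": perplexity, "seed": seed},
    )
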