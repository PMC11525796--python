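"""GRN-recovery benchmarking: edge scorers, AUPRC, precision-at-k.

The harness takes any edge scorer -- a callable mapping an expression matrix
to scores over all TF x gene pairs, or an external tool's (tf, gene, score)
TSV -- and evaluates it against ground-truth graphs (typically the positive
and negative control graphs).  Evaluation is undirected and unsigned; the
candidate universe defaults to all TF x gene pairs present in the data.  Two
baseline scorers are built in: absolute Spearman correlation and
ridge-regularized partial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .grn import RegulatoryGraph

Edge = tuple[str, str]


@dataclass
class EdgeScores:
    """Finite scores over a candidate universe of TF -> gene pairs."""

    scores: dict[Edge, float]
    tfs: tuple[str, ...]
    genes: tuple[str, ...]

    def __post_init__(self):
        vals = np.array(list(self.scores.values()), dtype=float)
        if len(vals) and not np.all(np.isfinite(vals)):
            raise ValueError("edge scores must be finite")

    @property
    def universe(self) -> list[Edge]:
        return sorted(self.scores)

    def check_covers(self, truth: RegulatoryGraph) -> None:
        missing = truth.edges - set(self.scores)
        if missing:
            raise ValueError(
                f"{len(missing)} ground-truth edges outside the scored "
                f"universe, e.g. {sorted(missing)[:3]}"
            )

    def top_k_per_gene(self, k: int) -> dict[str, list[str]]:
        by_gene: dict[str, list[tuple[float, str]]] = {g: [] for g in self.genes}
        for (tf, gene), s in self.scores.items():
            by_gene[gene].append((s, tf))
        out = {}
        for gene, cand in by_gene.items():
            if len(cand) < k:
                raise ValueError(f"gene {gene!r} has only {len(cand)} scored TFs")
            cand.sort(key=lambda st: (-st[0], st[1]))  # score desc, name asc
            out[gene] = [tf for _, tf in cand[:k]]
        return out

    def ranked_tfs_per_gene(self) -> dict[str, list[tuple[str, float]]]:
        """Per-gene (tf, score) lists ranked by score desc, name asc --
        the input format of the control-GRN constructor."""
        by_gene: dict[str, list[tuple[str, float]]] = {g: [] for g in self.genes}
        for (tf, gene), s in self.scores.items():
            by_gene[gene].append((tf, s))
        for cand in by_gene.values():
            cand.sort(key=lambda ts: (-ts[1], ts[0]))
        return by_gene


def _tf_gene_blocks(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    tf_idx = np.where(m.is_tf)[0]
    gene_idx = np.where(~m.is_tf)[0]
    if len(tf_idx) == 0 or len(gene_idx) == 0:
        raise ValueError("matrix must contain both TFs and genes (is_tf flags)")
    return (
        m.values[:, tf_idx],
        m.values[:, gene_idx],
        [m.feature_ids[i] for i in tf_idx],
        [m.feature_ids[i] for i in gene_idx],
    )


def score_edges_corr(m: ExpressionMatrix) -> EdgeScores:
    """|Spearman correlation| between every TF and every gene.

    Constant features score 0 against everything.
    """
    tf_vals, gene_vals, tfs, genes = _tf_gene_blocks(m)
    tr = np.apply_along_axis(stats.rankdata, 0, tf_vals)
    gr = np.apply_along_axis(stats.rankdata, 0, gene_vals)

    def _std_cols(a):
        a = a - a.mean(axis=0)
        sd = a.std(axis=0)
        ok = sd > 0
        a = np.divide(a, np.where(ok, sd, 1.0))
        a[:, ~ok] = 0.0
        return a

    n = tr.shape[0]
    corr = _std_cols(tr).T @ _std_cols(gr) / n
    scores = {
        (tfs[i], genes[j]): float(abs(corr[i, j]))
        for i in range(len(tfs))
        for j in range(len(genes))
    }
    return EdgeScores(scores, tuple(tfs), tuple(genes))


def score_edges_pcor(m: ExpressionMatrix, ridge: float | None = None) -> EdgeScores:
    """|partial correlation| of each gene with each TF given the other TFs.

    Precision-matrix based on the joint covariance of [all TFs, one gene];
    a small ridge (relative to the mean variance) keeps the matrix
    invertible when TFs are collinear.
    """
    tf_vals, gene_vals, tfs, genes = _tf_gene_blocks(m)
    n_tfs = len(tfs)
    scores: dict[Edge, float] = {}
    for j, gene in enumerate(genes):
        data = np.column_stack([tf_vals, gene_vals[:, j]])
        cov = np.cov(data, rowvar=False)
        lam = ridge if ridge is not None else 1e-6 * np.trace(cov) / cov.shape[0]
        prec = np.linalg.inv(cov + lam * np.eye(cov.shape[0]))
        d = np.sqrt(np.diag(prec))
        for i, tf in enumerate(tfs):
            pc = -prec[i, n_tfs] / (d[i] * d[n_tfs])
            scores[(tf, gene)] = float(abs(pc))
    return EdgeScores(scores, tuple(tfs), tuple(genes))


def load_edge_scores(path: str | Path) -> EdgeScores:
    """Adapter for external tools: read a (tf, gene, score) TSV/CSV."""
    sep = "\t" if Path(path).suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        df = pd.read_csv(path, sep=sep, header=None)
    tf_c, gene_c, score_c = df.columns[:3]
    scores = {
        (str(r[tf_c]), str(r[gene_c])): float(r[score_c])
        for _, r in df.iterrows()
    }
    tfs = tuple(sorted({t for t, _ in scores}))
    genes = tuple(sorted({g for _, g in scores}))
    return EdgeScores(scores, tfs, genes)


def auprc(scores: EdgeScores, truth: RegulatoryGraph) -> float:
    """Area under the precision-recall curve of the ranked candidate edges.

    Step-wise (average-precision) integration with tied scores grouped into
    one threshold, invariant to strictly monotone score transforms.
    """
    from sklearn.metrics import average_precision_score

    scores.check_covers(truth)
    universe = scores.universe
    if not truth.edges:
        raise ValueError("empty ground truth")
    y_true = np.array([e in truth.edges for e in universe], dtype=int)
    y_score = np.array([scores.scores[e] for e in universe])
    return float(average_precision_score(y_true, y_score))


def precision_at_k_per_gene(
    scores: EdgeScores, truth: RegulatoryGraph, k: int
) -> float:
    """Precision of the graph formed by each gene's top-``k`` scored TFs."""
    scores.check_covers(truth)
    top = scores.top_k_per_gene(k)
    genes = [g for g in scores.genes if g in set(truth.genes)]
    if not genes:
        raise ValueError("no ground-truth genes in the scored universe")
    hits = sum(
        (tf, gene) in truth.edges for gene in genes for tf in top[gene]
    )
    return hits / (k * len(genes))


def prevalence(scores: EdgeScores, truth: RegulatoryGraph) -> float:
    """Random-guessing AUPRC baseline: |truth| / |universe|."""
    return len(truth.edges) / len(scores.scores)


Scorer = Callable[[ExpressionMatrix], EdgeScores]

BUILTIN_SCORERS: dict[str, Scorer] = {
    "corr": score_edges_corr,
    "pcor": score_edges_pcor,
}


@dataclass
class BenchmarkReport:
    """Per-scorer AUPRC and precision-at-k against each control graph."""

    results: dict[str, dict[str, dict[str, float]]]
    prevalence: dict[str, float]
    k: int

    def to_dict(self) -> dict:
        return asdict(self)


def run_benchmark(
    sim: ExpressionMatrix,
    positive: RegulatoryGraph,
    negative: RegulatoryGraph,
    scorers: Mapping[str, Scorer] | Sequence[str] | None = None,
    k: int | None = None,
) -> BenchmarkReport:
    """Score the simulated data and evaluate against both control graphs.

    ``k`` for precision-at-k defaults to the positive graph's modal
    in-degree (the control graphs have constant in-degree by construction).
    """
    if scorers is None:
        scorers = BUILTIN_SCORERS
    elif not isinstance(scorers, Mapping):
        scorers = {name: BUILTIN_SCORERS[name] for name in scorers}
    degrees = [len(positive.parents(g)) for g in positive.genes]
    if k is None:
        k = int(np.bincount(degrees).argmax())
    results: dict[str, dict[str, dict[str, float]]] = {}
    prev: dict[str, float] = {}
    for name, scorer in scorers.items():
        es = scorer(sim)
        results[name] = {}
        for label, truth in (("positive", positive), ("negative", negative)):
            results[name][label] = {
                "auprc": auprc(es, truth),
                "precision_at_k": precision_at_k_per_gene(es, truth, k),
            }
            prev[label] = prevalence(es, truth)
    return BenchmarkReport(results=results, prevalence=prev, k=k)
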