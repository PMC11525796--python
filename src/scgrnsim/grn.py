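"""Bipartite TF -> gene regulatory graphs.

A regulatory graph here is a bipartite directed acyclic graph: every edge
runs from a transcription factor (TF) to a target gene, a name is never both
a TF and a target, every gene has at least one regulator, and every listed TF
regulates at least one gene.  Acyclicity is therefore structural.  The module
also builds the positive/negative control graphs used to test whether an
imposed network can be recovered from simulated data: for each gene the
odd-ranked TFs of its top-``n`` ranked regulators form the positive (imposed)
graph and the even-ranked TFs the negative (unimposed) graph, giving two
graphs of identical density.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Edge = tuple[str, str]

_HEADER_TOKENS = {"tf", "tfs", "regulator", "source", "gene", "target", "targets",
                  "score", "importance", "weight", "value"}


@dataclass(frozen=True)
class RegulatoryGraph:
    """Validated bipartite TF->gene graph with optional edge scores."""

    tfs: tuple[str, ...]
    genes: tuple[str, ...]
    edges: frozenset[Edge]
    scores: Mapping[Edge, float] | None = None

    def __post_init__(self):
        tfset, geneset = set(self.tfs), set(self.genes)
        overlap = tfset & geneset
        if overlap:
            raise ValueError(
                "bipartite violation: name(s) appear as both TF and target: "
                + ", ".join(sorted(overlap)[:5])
            )
        if not self.edges:
            raise ValueError("graph has no edges")
        for tf, gene in self.edges:
            if tf not in tfset or gene not in geneset:
                raise ValueError(f"edge ({tf!r}, {gene!r}) references unknown node")
        childless = tfset - {tf for tf, _ in self.edges}
        if childless:
            raise ValueError(
                "TF(s) with no targets: " + ", ".join(sorted(childless)[:5])
            )
        orphans = geneset - {g for _, g in self.edges}
        if orphans:
            raise ValueError(
                "gene(s) with no regulators: " + ", ".join(sorted(orphans)[:5])
            )
        if self.scores is not None:
            bad = set(self.scores) - self.edges
            if bad:
                raise ValueError(f"scores given for non-edges: {sorted(bad)[:5]}")

    # -- queries ----------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents(self, gene: str) -> tuple[str, ...]:
        """Regulating TFs of a gene, in a deterministic (name-sorted) order."""
        return tuple(sorted(tf for tf, g in self.edges if g == gene))

    def children(self, tf: str) -> tuple[str, ...]:
        return tuple(sorted(g for t, g in self.edges if t == tf))

    def parent_map(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {g: [] for g in self.genes}
        for tf, g in self.edges:
            out[g].append(tf)
        return {g: tuple(sorted(v)) for g, v in out.items()}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.tfs, kind="tf")
        g.add_nodes_from(self.genes, kind="gene")
        for tf, gene in self.edges:
            w = None if self.scores is None else self.scores.get((tf, gene))
            g.add_edge(tf, gene, **({} if w is None else {"score": w}))
        return g

    # -- io ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        df = pd.DataFrame(rows, columns=["tf", "gene"])
        if self.scores is not None:
            df["score"] = [self.scores.get(e, np.nan) for e in rows]
        return df

    def save(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _ordered_unique(items: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x, None)
    return tuple(seen)


def from_edges(
    edges: Iterable[Edge | tuple[str, str, float]],
    scores: Mapping[Edge, float] | None = None,
) -> RegulatoryGraph:
    """Build a graph from (tf, gene[, score]) tuples, collapsing duplicates.

    Duplicate edges keep the maximum score.
    """
    edge_set: dict[Edge, None] = {}
    score_map: dict[Edge, float] = dict(scores or {})
    has_scores = bool(score_map)
    for item in edges:
        if len(item) == 3:
            tf, gene, s = item  # type: ignore[misc]
            key = (str(tf), str(gene))
            s = float(s)
            score_map[key] = max(score_map.get(key, -np.inf), s)
            has_scores = True
        else:
            tf, gene = item  # type: ignore[misc]
            key = (str(tf), str(gene))
        edge_set.setdefault(key, None)
    tfs = _ordered_unique(tf for tf, _ in edge_set)
    genes = _ordered_unique(g for _, g in edge_set)
    return RegulatoryGraph(
        tfs=tfs,
        genes=genes,
        edges=frozenset(edge_set),
        scores=score_map if has_scores else None,
    )


def _looks_like_header(row: Sequence[str]) -> bool:
    if len(row) >= 3:
        try:
            float(row[2])
            return False
        except (TypeError, ValueError):
            return True
    return any(str(tok).strip().lower() in _HEADER_TOKENS for tok in row)


def load_grn(path: str | Path, tf_list: Iterable[str] | None = None) -> RegulatoryGraph:
    """Read an edge list (TSV or CSV; optional header; optional score column).

    If ``tf_list`` is given, every regulator must be in it (a stand-in for a
    TF annotation database); otherwise the first column defines the TF set.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty GRN file: {path}")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns (TF, gene)")
    if _looks_like_header(df.iloc[0].tolist()):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no edges in GRN file: {path}")
    if df.shape[1] >= 3:
        triples = [
            (r[0], r[1], float(r[2])) for r in df.itertuples(index=False)
        ]
        graph = from_edges(triples)
    else:
        graph = from_edges([(r[0], r[1]) for r in df.itertuples(index=False)])
    if tf_list is not None:
        unknown = set(graph.tfs) - set(tf_list)
        if unknown:
            raise ValueError(
                "regulators not in the provided TF list: "
                + ", ".join(sorted(unknown)[:5])
            )
    return graph


RankedInput = Mapping[str, Sequence[str] | Sequence[tuple[str, float]]]


def _normalize_ranked(ranked: RankedInput) -> dict[str, list[str]]:
    """Sort each gene's candidates by (score desc, name asc); plain lists keep order."""
    out: dict[str, list[str]] = {}
    for gene, cand in ranked.items():
        cand = list(cand)
        if cand and isinstance(cand[0], (tuple, list)):
            cand = [t for t, _ in sorted(cand, key=lambda ts: (-float(ts[1]), ts[0]))]
        out[str(gene)] = [str(c) for c in cand]
    return out


def make_control_grns(
    ranked: RankedInput, top_n: int = 10
) -> tuple[RegulatoryGraph, RegulatoryGraph]:
    """Positive (odd ranks) and negative (even ranks) control graphs.

    For each gene the ``top_n`` highest-ranked candidate TFs are split by
    parity: ranks 1, 3, 5, ... form the positive control (to be imposed) and
    ranks 2, 4, 6, ... the negative control.  The two graphs have identical
    densities by construction; whether they share the same TF set depends on
    the rankings and is reported via :func:`control_tf_sets_equal`.
    """
    ranked_n = _normalize_ranked(ranked)
    pos_edges: list[Edge] = []
    neg_edges: list[Edge] = []
    for gene, cand in sorted(ranked_n.items()):
        if len(cand) < top_n:
            raise ValueError(
                f"gene {gene!r} has only {len(cand)} ranked TFs (< top_n={top_n})"
            )
        top = cand[:top_n]
        pos_edges.extend((tf, gene) for tf in top[0::2])
        neg_edges.extend((tf, gene) for tf in top[1::2])
    positive = from_edges(pos_edges)
    negative = from_edges(neg_edges)
    assert positive.n_edges == negative.n_edges, "control densities must match"
    return positive, negative


def control_tf_sets_equal(pos: RegulatoryGraph, neg: RegulatoryGraph) -> bool:
    return set(pos.tfs) == set(neg.tfs)


def random_grn(
    genes: Sequence[str], tfs: Sequence[str], k: int, seed: int
) -> RegulatoryGraph:
    """Assign each gene exactly ``k`` distinct TFs uniformly at random."""
    tfs = list(tfs)
    if k > len(tfs):
        raise ValueError(f"k={k} exceeds number of TFs ({len(tfs)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    edges: list[Edge] = []
    for gene in genes:
        chosen = rng.choice(len(tfs), size=k, replace=False)
        edges.extend((tfs[i], str(gene)) for i in sorted(chosen))
    # a TF drawn for no gene would violate the no-childless-TF invariant;
    # restrict the declared TF set to those actually used
    return from_edges(edges)
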