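"""Edge scorers, AUPRC, precision-at-k, and the benchmark harness."""

import numpy as np
import pytest

from scgrnsim.benchmark import (
    EdgeScores,
    auprc,
    load_edge_scores,
    precision_at_k_per_gene,
    prevalence,
    run_benchmark,
    score_edges_corr,
    score_edges_pcor,
)
from scgrnsim.expression import ExpressionMatrix
from scgrnsim.grn import from_edges
from scgrnsim.synthetic import SyntheticConfig, simulate_reference


def em_from_columns(cols: dict, tfs: set) -> ExpressionMatrix:
    names = list(cols)
    values = np.column_stack([np.asarray(cols[n], dtype=float) for n in names])
    return ExpressionMatrix(
        values, [f"c{i}" for i in range(values.shape[0])], names,
        np.array([n in tfs for n in names]),
    )


class TestCorrScorer:
    def test_exact_linear_dependence_scores_one(self):
        rng = np.random.default_rng(0)
        t = rng.gamma(2.0, 1.0, 100)
        m = em_from_columns({"T1": t, "G1": 2 * t}, {"T1"})
        assert score_edges_corr(m).scores[("T1", "G1")] == pytest.approx(1.0)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(1)
        m = em_from_columns(
            {"T1": rng.gamma(2, 1, 2000), "G1": rng.gamma(2, 1, 2000)}, {"T1"}
        )
        assert score_edges_corr(m).scores[("T1", "G1")] < 0.1

    def test_constant_feature_scores_zero(self):
        rng = np.random.default_rng(2)
        m = em_from_columns(
            {"T1": np.full(50, 3.0), "G1": rng.gamma(2, 1, 50)}, {"T1"}
        )
        assert score_edges_corr(m).scores[("T1", "G1")] == 0.0

    def test_true_edges_outrank_false_on_scm_fixture(self):
        em, g = simulate_reference(SyntheticConfig(seed=8))
        es = score_edges_corr(em)
        true_scores = [es.scores[e] for e in g.edges]
        false_scores = [
            s for e, s in es.scores.items() if e not in g.edges
        ]
        assert np.mean(true_scores) > np.mean(false_scores)


class TestPcorScorer:
    def test_exact_linear_parent_scores_high(self):
        rng = np.random.default_rng(3)
        t1, t2 = rng.gamma(2, 1, 500), rng.gamma(2, 1, 500)
        m = em_from_columns(
            {"T1": t1, "T2": t2, "G1": 3 * t1 + rng.normal(0, 0.01, 500)},
            {"T1", "T2"},
        )
        es = score_edges_pcor(m)
        assert es.scores[("T1", "G1")] > 0.9

    def test_conditionally_independent_tf_scores_near_zero(self):
        # G1 depends on T1 only; T2 correlates with G1 *through* T1
        rng = np.random.default_rng(4)
        t1 = rng.gamma(2, 1, 3000)
        t2 = np.maximum(t1 + rng.normal(0, 0.5, 3000), 0.0)
        g1 = np.maximum(2 * t1 + rng.normal(0, 0.1, 3000), 0.0)
        m = em_from_columns({"T1": t1, "T2": t2, "G1": g1}, {"T1", "T2"})
        es = score_edges_pcor(m)
        assert es.scores[("T2", "G1")] < 0.2
        assert es.scores[("T1", "G1")] > 0.8

    def test_true_edges_outrank_false_on_scm_fixture(self):
        em, g = simulate_reference(
            SyntheticConfig(regulation="linear", seed=9)
        )
        es = score_edges_pcor(em)
        true_scores = [es.scores[e] for e in g.edges]
        false_scores = [s for e, s in es.scores.items() if e not in g.edges]
        assert np.mean(true_scores) > np.mean(false_scores)


def brute_force_auprc(pairs):
    """Step-wise PR integration over grouped score thresholds."""
    order = sorted({s for s, _ in pairs}, reverse=True)
    n_true = sum(t for _, t in pairs)
    area, prev_recall = 0.0, 0.0
    for thr in order:
        sel = [(s, t) for s, t in pairs if s >= thr]
        tp = sum(t for _, t in sel)
        precision = tp / len(sel)
        recall = tp / n_true
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestAuprc:
    TRUTH = from_edges([("T1", "G1"), ("T2", "G1")])

    def scores(self, vals):
        keys = [("T1", "G1"), ("T2", "G1"), ("T3", "G1"), ("T4", "G1")]
        return EdgeScores(dict(zip(keys, vals)), ("T1", "T2", "T3", "T4"), ("G1",))

    def test_perfect_separation_gives_one(self):
        es = self.scores([0.9, 0.8, 0.1, 0.0])
        assert auprc(es, self.TRUTH) == pytest.approx(1.0)

    def test_toy_matches_brute_force_enumeration(self):
        es = self.scores([0.9, 0.7, 0.8, 0.1])  # ranked: T(0.9) F(0.8) T(0.7) F(0.1)
        pairs = [(0.9, 1), (0.8, 0), (0.7, 1), (0.1, 0)]
        assert auprc(es, self.TRUTH) == pytest.approx(brute_force_auprc(pairs))

    def test_random_scores_near_prevalence(self):
        rng = np.random.default_rng(5)
        tfs = [f"T{i}" for i in range(20)]
        genes = [f"G{j}" for j in range(50)]
        truth = from_edges([(tfs[rng.integers(0, 20)], g) for g in genes])
        scores = EdgeScores(
            {(t, g): float(rng.random()) for t in tfs for g in genes},
            tuple(tfs), tuple(genes),
        )
        p = prevalence(scores, truth)
        vals = [
            auprc(
                EdgeScores({k: float(r) for k, r in
                            zip(scores.scores, rng.random(len(scores.scores)))},
                           scores.tfs, scores.genes),
                truth,
            )
            for _ in range(10)
        ]
        assert abs(np.mean(vals) - p) < 0.05

    def test_invariant_to_monotone_transform(self):
        es = self.scores([0.9, 0.7, 0.8, 0.1])
        transformed = self.scores([np.log(s + 1) * 10 for s in [0.9, 0.7, 0.8, 0.1]])
        assert auprc(es, self.TRUTH) == pytest.approx(auprc(transformed, self.TRUTH))

    def test_truth_outside_universe_rejected(self):
        es = self.scores([0.9, 0.7, 0.8, 0.1])
        with pytest.raises(ValueError, match="universe"):
            auprc(es, from_edges([("TX", "G1")]))


class TestPrecisionAtK:
    def test_perfect_scores_give_one(self):
        truth = from_edges([("T1", "G1"), ("T2", "G1")])
        es = EdgeScores(
            {("T1", "G1"): 0.9, ("T2", "G1"): 0.8, ("T3", "G1"): 0.1},
            ("T1", "T2", "T3"), ("G1",),
        )
        assert precision_at_k_per_gene(es, truth, k=2) == 1.0

    def test_anticorrelated_scores_give_zero(self):
        truth = from_edges([("T1", "G1"), ("T2", "G1")])
        es = EdgeScores(
            {("T1", "G1"): 0.0, ("T2", "G1"): 0.1, ("T3", "G1"): 0.9,
             ("T4", "G1"): 0.8},
            ("T1", "T2", "T3", "T4"), ("G1",),
        )
        assert precision_at_k_per_gene(es, truth, k=2) == 0.0

    def test_three_gene_mixed_hits_match_hand_count(self):
        truth = from_edges(
            [("T1", "G1"), ("T2", "G2"), ("T3", "G3"), ("T1", "G3")]
        )
        scores = {}
        for g in ("G1", "G2", "G3"):
            for i, t in enumerate(("T1", "T2", "T3")):
                scores[(t, g)] = 0.0
        scores[("T1", "G1")] = 0.9   # hit
        scores[("T3", "G1")] = 0.8   # miss
        scores[("T1", "G2")] = 0.9   # miss
        scores[("T2", "G2")] = 0.8   # hit
        scores[("T3", "G3")] = 0.9   # hit
        scores[("T1", "G3")] = 0.8   # hit
        es = EdgeScores(scores, ("T1", "T2", "T3"), ("G1", "G2", "G3"))
        # 4 hits of 6 predictions at k=2
        assert precision_at_k_per_gene(es, truth, k=2) == pytest.approx(4 / 6)

    def test_insufficient_candidates_rejected(self):
        truth = from_edges([("T1", "G1")])
        es = EdgeScores({("T1", "G1"): 1.0}, ("T1",), ("G1",))
        with pytest.raises(ValueError, match="only"):
            precision_at_k_per_gene(es, truth, k=5)


class TestHarness:
    def test_oracle_scorer_reaches_auprc_one(self):
        em, g = simulate_reference(SyntheticConfig(n_cells=100, seed=10))
        neg = from_edges(
            [(t, gene) for gene in g.genes for t in g.tfs
             if t not in g.parents(gene)][: g.n_edges]
        )

        def oracle(m):
            es = score_edges_corr(m)
            return EdgeScores(
                {e: (1.0 if e in g.edges else 0.0) for e in es.scores},
                es.tfs, es.genes,
            )

        report = run_benchmark(em, g, neg, scorers={"oracle": oracle})
        assert report.results["oracle"]["positive"]["auprc"] == pytest.approx(1.0)
        assert report.prevalence["positive"] == pytest.approx(
            g.n_edges / (len(g.tfs) * len(g.genes))
        )

    def test_external_score_file_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"tf": ["T1", "T2"], "gene": ["G1", "G1"], "score": [0.9, 0.2]}
        )
        path = tmp_path / "scores.tsv"
        df.to_csv(path, sep="\t", index=False)
        es = load_edge_scores(path)
        assert es.scores[("T1", "G1")] == 0.9
        assert es.tfs == ("T1", "T2")
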