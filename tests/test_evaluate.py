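"""Benchmark metrics against explicit precision-recall oracles, and the
robustness perturbation generators."""

import numpy as np
import pandas as pd
import pytest

import reggain as rg
from reggain.data import GroundTruthNetwork, PriorNetwork
from reggain.evaluate import (
    auprc_ratio,
    corrupt_prior,
    downsample_cells,
    epr,
    evaluation_universe,
    random_prior_baseline,
    remove_prior_edges,
)


def oracle_average_precision(scores, labels):
    """Step-wise AP over distinct score thresholds (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_true = labels.sum()
    ap, tp, fp = 0.0, 0, 0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        sel = scores == t
        tp += int(labels[sel].sum())
        fp += int((~labels[sel].astype(bool)).sum())
        recall = tp / n_true
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def oracle_early_precision(universe, scores, labels, k):
    order = sorted(range(len(universe)), key=lambda i: (-scores[i], universe[i]))
    return sum(labels[i] for i in order[:k]) / k


def scores_frame(universe, values):
    return pd.DataFrame(
        {"tf": [a for a, _ in universe],
         "target": [b for _, b in universe],
         "score": values}
    )


@pytest.fixture()
def toy_problem(rng):
    genes = [f"tf{i}" for i in range(4)] + [f"g{i}" for i in range(10)]
    truth_edges = set()
    while len(truth_edges) < 12:
        a = f"tf{rng.integers(4)}"
        b = genes[rng.integers(len(genes))]
        if a != b:
            truth_edges.add((a, b))
    truth = GroundTruthNetwork(truth_edges, {f"tf{i}" for i in range(4)})
    universe = evaluation_universe(genes, truth)
    return genes, truth, universe


class TestMetricOracles:
    def test_auprc_matches_pr_curve_oracle(self, toy_problem, rng):
        genes, truth, universe = toy_problem
        labels = np.array([e in truth.edges for e in universe], dtype=int)
        for _ in range(5):
            # quantized scores force ties through the tie-handling path
            values = np.round(rng.normal(size=len(universe)), 1)
            res = auprc_ratio(scores_frame(universe, values), truth, genes)
            ap = oracle_average_precision(values, labels)
            assert res.auprc == pytest.approx(ap, abs=1e-9)
            assert res.auprc_ratio == pytest.approx(
                ap / labels.mean(), abs=1e-9
            )

    def test_epr_matches_topk_oracle(self, toy_problem, rng):
        genes, truth, universe = toy_problem
        labels = np.array([e in truth.edges for e in universe], dtype=int)
        k = int(labels.sum())
        values = np.round(rng.normal(size=len(universe)), 1)
        out = epr(scores_frame(universe, values), truth, genes)
        ep = oracle_early_precision(universe, values, labels, k)
        assert out == pytest.approx(ep / labels.mean(), abs=1e-9)

    def test_perfect_ranking_ratio_is_inverse_density(self, toy_problem):
        genes, truth, universe = toy_problem
        values = [1.0 if e in truth.edges else 0.0 for e in universe]
        res = auprc_ratio(scores_frame(universe, values), truth, genes)
        density = res.truth_count / res.candidate_count
        assert res.auprc == pytest.approx(1.0)
        assert res.auprc_ratio == pytest.approx(1.0 / density)
        assert res.epr == pytest.approx(1.0 / density)

    def test_all_equal_scores_give_ratio_one(self, toy_problem):
        genes, truth, universe = toy_problem
        res = auprc_ratio(scores_frame(universe, np.ones(len(universe))), truth, genes)
        assert res.auprc_ratio == pytest.approx(1.0, abs=1e-9)

    def test_unscored_candidates_sink_to_bottom(self, toy_problem):
        genes, truth, universe = toy_problem
        true_only = [e for e in universe if e in truth.edges]
        res = auprc_ratio(
            scores_frame(true_only, np.ones(len(true_only))), truth, genes
        )
        # scoring only the true edges at the top is a perfect ranking
        assert res.auprc == pytest.approx(1.0)

    def test_degenerate_full_truth_epr_is_one(self):
        truth = GroundTruthNetwork({("tf0", "g0"), ("tf0", "g1")}, {"tf0"})
        genes = ["tf0", "g0", "g1"]
        universe = evaluation_universe(genes, truth)
        assert len(universe) == 2
        out = epr(scores_frame(universe, [0.1, 0.9]), truth, genes)
        assert out == pytest.approx(1.0)

    def test_empty_truth_intersection_raises(self):
        truth = GroundTruthNetwork({("tfZ", "gZ")}, {"tfZ"})
        with pytest.raises(ValueError):
            auprc_ratio(pd.DataFrame(columns=["tf", "target", "score"]),
                        truth, ["a", "b"])

    def test_k_beyond_universe_raises(self, toy_problem):
        genes, truth, universe = toy_problem
        with pytest.raises(ValueError):
            epr(scores_frame(universe, np.ones(len(universe))), truth, genes,
                k=len(universe) + 1)


@pytest.fixture()
def dense_prior(rng):
    n = 40
    genes = [f"g{i:02d}" for i in range(n)]
    edges = set()
    while len(edges) < 200:
        i, j = (int(v) for v in rng.integers(n, size=2))
        if i != j:
            edges.add((i, j))
    return PriorNetwork(genes, edges)


class TestPerturbations:
    def test_remove_zero_fraction_identity(self, dense_prior):
        out = remove_prior_edges(dense_prior, 0.0, seed=1)
        assert out.edges == dense_prior.edges

    def test_remove_exact_count_and_nodes_kept(self, dense_prior):
        out = remove_prior_edges(dense_prior, 0.5, seed=1)
        assert out.n_edges == 100
        assert out.gene_ids == dense_prior.gene_ids
        assert out.edges <= dense_prior.edges

    def test_removal_seeds_give_distinct_edge_sets(self, dense_prior):
        sets = {
            frozenset(remove_prior_edges(dense_prior, 0.3, seed=s).edges)
            for s in range(10)
        }
        assert len(sets) == 10

    def test_downsample_cells_exact(self, tiny_case):
        X = tiny_case.expression
        out = downsample_cells(X, 0.5, seed=2)
        assert out.n_cells == X.n_cells - round(0.5 * X.n_cells)
        assert out.gene_ids == X.gene_ids
        assert downsample_cells(X, 0.0, seed=2).n_cells == X.n_cells

    def test_random_swap_conserves_count_and_overlap(self, dense_prior):
        out = corrupt_prior(dense_prior, 0.3, "random-swap", seed=3)
        assert out.n_edges == dense_prior.n_edges
        expected_kept = dense_prior.n_edges - round(0.3 * dense_prior.n_edges)
        assert len(out.edges & dense_prior.edges) == expected_kept

    def test_degree_preserving_swap_keeps_degree_sequences(self, dense_prior):
        out = corrupt_prior(dense_prior, 0.3, "degree-preserving-swap", seed=4)
        assert out.n_edges == dense_prior.n_edges

        def seqs(net):
            n = net.n_genes
            ind = np.zeros(n, dtype=int)
            outd = np.zeros(n, dtype=int)
            for i, j in net.edges:
                outd[i] += 1
                ind[j] += 1
            return ind, outd

        i0, o0 = seqs(dense_prior)
        i1, o1 = seqs(out)
        assert np.array_equal(i0, i1) and np.array_equal(o0, o1)
        displaced = len(out.edges - dense_prior.edges)
        assert displaced >= round(0.3 * dense_prior.n_edges)

    def test_corrupt_zero_fraction_identity(self, dense_prior):
        for mode in ("random-swap", "degree-preserving-swap"):
            out = corrupt_prior(dense_prior, 0.0, mode, seed=5)
            assert out.edges == dense_prior.edges


class TestRandomPriorBaseline:
    def test_all_sources_are_tfs_and_reproducible(self, dense_prior):
        tfs = {g for g in dense_prior.gene_ids[:8]}
        a = random_prior_baseline(dense_prior, tfs, 20, seed=6)
        b = random_prior_baseline(dense_prior, tfs, 20, seed=6)
        assert set(a.edges["tf"]) <= tfs
        assert a.edges.equals(b.edges)

    def test_oversized_h_returns_whole_tf_prior(self, dense_prior):
        tfs = {g for g in dense_prior.gene_ids[:8]}
        n_candidates = sum(
            1 for i, j in dense_prior.edges if dense_prior.gene_ids[i] in tfs
        )
        grn = random_prior_baseline(dense_prior, tfs, 10_000, seed=7)
        assert len(grn.edges) == n_candidates
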