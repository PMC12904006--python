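"""Clustering, target-set similarity, co-clustering curves, differential
out-degree ranking and the motif hit-ratio statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reggain as rg
from reggain.downstream import (
    ClusterAssignment,
    cluster_embeddings,
    co_cluster_curve,
    differential_out_degree,
    ranked_tf_pairs,
    set_similarity,
    target_jaccard,
    tf_hit_ratio,
)
from reggain.inference import InferredGRN, RegulatoryScoreMatrix


def grn_from_edges(edges, scores=None):
    df = pd.DataFrame(edges, columns=["tf", "target"])
    df["score"] = scores if scores is not None else np.linspace(1, 0.1, len(df))
    df["rank"] = range(1, len(df) + 1)
    return InferredGRN(df, set(df["tf"]))


class TestClusterEmbeddings:
    def test_separated_blobs_recovered_by_kmeans(self, rng):
        a = rng.normal(size=(20, 5))
        b = rng.normal(size=(20, 5)) + 30.0  # 10+ sigma separation
        emb = np.vstack([a, b])
        genes = [f"g{i}" for i in range(40)]
        out = cluster_embeddings(emb, genes, "kmeans", 2, seed=0)
        labels = np.array([out.labels[g] for g in genes])
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_singletons(self, rng):
        emb = rng.normal(size=(6, 3))
        genes = [f"g{i}" for i in range(6)]
        out = cluster_embeddings(emb, genes, "kmeans", 6, seed=1)
        assert len(set(out.labels.values())) == 6

    def test_same_seed_identical_labels(self, rng):
        emb = rng.normal(size=(30, 4))
        genes = [f"g{i}" for i in range(30)]
        for method, param in [("kmeans", 3), ("leiden", 1.0)]:
            a = cluster_embeddings(emb, genes, method, param, seed=5)
            b = cluster_embeddings(emb, genes, method, param, seed=5)
            assert a.labels == b.labels

    def test_leiden_blobs_and_contiguous_labels(self, rng):
        a = rng.normal(size=(15, 4))
        b = rng.normal(size=(15, 4)) + 25.0
        genes = [f"g{i}" for i in range(30)]
        out = cluster_embeddings(np.vstack([a, b]), genes, "leiden", 0.5, seed=2)
        labels = sorted(set(out.labels.values()))
        assert labels == list(range(len(labels)))
        assert out.labels["g0"] != out.labels["g29"]

    def test_invalid_k_raises(self, rng):
        with pytest.raises(ValueError):
            cluster_embeddings(rng.normal(size=(4, 2)), list("abcd"), "kmeans", 9)


class TestTargetSimilarity:
    def test_identical_sets(self):
        grn = grn_from_edges([("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")])
        assert target_jaccard(grn, "a", "b") == 1.0

    def test_disjoint_sets(self):
        grn = grn_from_edges([("a", "x"), ("b", "y")])
        assert target_jaccard(grn, "a", "b") == 0.0

    def test_half_overlap(self):
        grn = grn_from_edges(
            [("a", "x"), ("a", "y"), ("a", "z"),
             ("b", "y"), ("b", "z"), ("b", "w")]
        )
        assert target_jaccard(grn, "a", "b") == pytest.approx(0.5)

    def test_missing_tf_gives_zero(self):
        grn = grn_from_edges([("a", "x")])
        assert target_jaccard(grn, "a", "nope") == 0.0

    @settings(deadline=None, max_examples=40)
    @given(
        st.sets(st.integers(0, 12), max_size=8),
        st.sets(st.integers(0, 12), max_size=8),
    )
    def test_similarity_metrics_bounded_and_symmetric(self, a, b):
        for metric in ("jaccard", "dice", "cosine", "kulczynski"):
            s = set_similarity(a, b, metric)
            assert 0 <= s <= 1
            assert s == set_similarity(b, a, metric)
            if a and a == b:
                assert s == 1.0


class TestCoClusterCurve:
    def labels(self, mapping):
        return ClusterAssignment(mapping, "kmeans", 2)

    def test_all_pairs_co_clustered_constant_one(self):
        labels = self.labels({"a": 0, "b": 0, "c": 0})
        pairs = [("a", "b", 0.9), ("a", "c", 0.8), ("b", "c", 0.7)]
        assert np.allclose(co_cluster_curve(pairs, labels, 3), 1.0)

    def test_hand_counted_sequence(self):
        labels = self.labels({"a": 0, "b": 0, "c": 1, "d": 1, "e": 2})
        pairs = [
            ("a", "b", 0.9),  # same -> 1/1
            ("a", "c", 0.8),  # diff -> 1/2
            ("c", "d", 0.7),  # same -> 2/3
            ("b", "e", 0.6),  # diff -> 2/4
            ("a", "d", 0.5),  # diff -> 2/5
        ]
        curve = co_cluster_curve(pairs, labels, 5)
        assert np.allclose(curve, [1, 0.5, 2 / 3, 0.5, 0.4])

    def test_truncates_with_warning(self):
        labels = self.labels({"a": 0, "b": 0})
        with pytest.warns(UserWarning):
            curve = co_cluster_curve([("a", "b", 1.0)], labels, 500)
        assert len(curve) == 1
        assert curve[0] in (0.0, 1.0)

    def test_ranked_tf_pairs_ordering(self):
        grn = grn_from_edges(
            [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y"), ("c", "z")]
        )
        pairs = ranked_tf_pairs(grn)
        assert pairs[0][:2] == ("a", "b") and pairs[0][2] == 1.0
        sims = [p[2] for p in pairs]
        assert sims == sorted(sims, reverse=True)


def matrices_for_groups(rng, genes, n_per_group, shift_edges=(), shift=0.0):
    out, groups = [], []
    idx = {g: i for i, g in enumerate(genes)}
    for group in ("A", "B"):
        for _ in range(n_per_group):
            m = rng.normal(size=(len(genes), len(genes)))
            np.fill_diagonal(m, 0)
            if group == "A":
                for a, b in shift_edges:
                    m[idx[a], idx[b]] += shift
            out.append(RegulatoryScoreMatrix(m, list(genes)))
            groups.append(group)
    return out, groups


class TestDifferentialOutDegree:
    genes = ["tf1", "tf2", "g1", "g2", "g3"]
    tfs = {"tf1", "tf2"}

    def test_null_case_scores_near_zero(self, rng):
        mats, groups = matrices_for_groups(rng, self.genes, 5)
        res = differential_out_degree(mats, groups, self.tfs, edges_per_gene=2)
        # at alpha=0.05 a few false positives are expected, but no TF
        # should accumulate a large net score under the null
        assert res.table["differential_out_degree"].abs().max() <= 2

    def test_planted_shift_detected(self, rng):
        shifted = [("tf1", "g1"), ("tf1", "g2"), ("tf1", "g3"),
                   ("tf1", "tf2"), ("tf2", "g1")]
        mats, groups = matrices_for_groups(
            rng, self.genes, 10, shifted, shift=8.0
        )
        res = differential_out_degree(
            mats, groups, self.tfs, edge_universe=shifted
        )
        row = res.table.set_index("tf")
        assert row.loc["tf1", "differential_out_degree"] == 4
        assert row.loc["tf2", "differential_out_degree"] == 1

    def test_swapping_groups_negates_scores(self, rng):
        shifted = [("tf1", "g1"), ("tf1", "g2")]
        mats, groups = matrices_for_groups(rng, self.genes, 6, shifted, 8.0)
        res = differential_out_degree(mats, groups, self.tfs, edge_universe=shifted)
        flipped = ["B" if g == "A" else "A" for g in groups]
        res2 = differential_out_degree(mats, flipped, self.tfs, edge_universe=shifted)
        a = res.table.set_index("tf")["differential_out_degree"]
        b = res2.table.set_index("tf")["differential_out_degree"]
        assert (a + b).abs().max() == 0

    def test_small_group_raises(self, rng):
        mats, groups = matrices_for_groups(rng, self.genes, 2)
        with pytest.raises(ValueError, match="3 samples"):
            differential_out_degree(mats, groups, self.tfs, edge_universe=[])

    def test_consistency_of_counts(self, rng):
        mats, groups = matrices_for_groups(rng, self.genes, 4)
        res = differential_out_degree(mats, groups, self.tfs, edges_per_gene=2)
        t = res.table
        assert (t["differential_out_degree"] == t["n_up"] - t["n_down"]).all()


class TestHitRatio:
    def test_direct_ratio(self):
        grn = grn_from_edges(
            [("a", "x"), ("b", "x"), ("c", "x"), ("d", "x")]
        )
        hits = pd.DataFrame(
            {"tf": list("abcd"), "gene": ["x"] * 4, "hit": [1, 1, 0, 0]}
        )
        res = tf_hit_ratio(grn, hits, top_fraction=1.0)
        assert res.per_gene.loc[0, "hit_ratio"] == pytest.approx(0.5)

    def test_all_hits(self):
        grn = grn_from_edges([("a", "x"), ("a", "y")])
        hits = pd.DataFrame(
            {"tf": ["a", "a"], "gene": ["x", "y"], "hit": [1, 1]}
        )
        res = tf_hit_ratio(grn, hits, top_fraction=1.0)
        assert (res.per_gene["hit_ratio"] == 1).all()
        assert res.nonzero_proportion == 1.0

    def test_twenty_edge_enumeration(self, rng):
        tfs = [f"tf{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(5)]
        edges = [(a, b) for a in tfs for b in genes]
        scores = rng.permutation(len(edges)) + 1.0
        grn = grn_from_edges(edges, scores)
        hit_flags = rng.integers(0, 2, size=len(edges))
        hits = pd.DataFrame(
            {"tf": [a for a, _ in edges],
             "gene": [b for _, b in edges],
             "hit": hit_flags}
        )
        res = tf_hit_ratio(grn, hits, top_fraction=0.5)
        # oracle: hand-group the top half
        order = np.argsort(-scores)[:10]
        expected = {}
        for ix in order:
            a, b = edges[ix]
            n, h = expected.get(b, (0, 0))
            expected[b] = (n + 1, h + hit_flags[ix])
        for _, row in res.per_gene.iterrows():
            n, h = expected[row["gene"]]
            assert row["n_predicted"] == n
            assert row["hit_ratio"] == pytest.approx(h / n)

    def test_invariant_to_hit_table_row_order(self, rng):
        grn = grn_from_edges([("a", "x"), ("b", "x"), ("a", "y")])
        hits = pd.DataFrame(
            {"tf": ["a", "b", "a"], "gene": ["x", "x", "y"], "hit": [1, 0, 1]}
        )
        r1 = tf_hit_ratio(grn, hits, 1.0)
        r2 = tf_hit_ratio(grn, hits.iloc[::-1].reset_index(drop=True), 1.0)
        assert r1.per_gene.equals(r2.per_gene)

    def test_missing_pairs_counted_as_zero(self):
        grn = grn_from_edges([("a", "x"), ("b", "x")])
        hits = pd.DataFrame({"tf": ["a"], "gene": ["x"], "hit": [1]})
        res = tf_hit_ratio(grn, hits, 1.0)
        assert res.per_gene.loc[0, "hit_ratio"] == pytest.approx(0.5)

    def test_empty_top_slice_raises(self):
        grn = grn_from_edges([("a", "x"), ("b", "y")])
        with pytest.raises(ValueError):
            tf_hit_ratio(grn, pd.DataFrame(columns=["tf", "gene", "hit"]), 0.05)
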