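"""Benchmark metrics and robustness perturbations.

AUPRC ratio and early-precision ratio (EPR) are computed over a fixed
candidate universe: (TFs present in the ground truth) x (genes in the
scored set), minus self-loops.  Candidates the method never scored count
at the bottom of the ranking, so missing edges are penalized rather than
silently excluded.  Both metrics are normalized by the ground-truth edge
density, the expected score of a random predictor, so 1.0 means random.

The perturbation generators emulate common data imperfections: missing
prior edges, reduced cell numbers, and false prior edges introduced by
either uniform random swaps or degree-preserving double-edge swaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .data import GeneExpressionMatrix, GroundTruthNetwork, PriorNetwork
from .inference import InferredGRN

__all__ = [
    "EvaluationResult",
    "evaluation_universe",
    "auprc_ratio",
    "epr",
    "evaluate_grn",
    "remove_prior_edges",
    "downsample_cells",
    "corrupt_prior",
    "random_prior_baseline",
]


@dataclass
class EvaluationResult:
    auprc: float
    auprc_ratio: float
    early_precision: float
    epr: float
    candidate_count: int
    truth_count: int


def evaluation_universe(
    scored_genes, truth: GroundTruthNetwork
) -> list[tuple[str, str]]:
    """(truth TFs) x (scored genes) minus self-loops, in deterministic order."""
    genes = sorted(set(scored_genes))
    tfs = sorted(truth.tf_set & set(genes))
    return [(a, b) for a in tfs for b in genes if a != b]


def _ranked_scores(
    scores: InferredGRN | pd.DataFrame | dict,
    universe: list[tuple[str, str]],
) -> np.ndarray:
    """Score vector over the universe; unscored candidates sink to the bottom."""
    if isinstance(scores, InferredGRN):
        scores = scores.edges
    if isinstance(scores, pd.DataFrame):
        lookup = {
            (a, b): s
            for a, b, s in zip(scores["tf"], scores["target"], scores["score"])
        }
    else:
        lookup = dict(scores)
    floor = (min(lookup.values()) if lookup else 0.0) - 1.0
    return np.array([lookup.get(pair, floor) for pair in universe])


def _truth_labels(
    truth: GroundTruthNetwork, universe: list[tuple[str, str]]
) -> np.ndarray:
    edges = truth.edges
    return np.array([pair in edges for pair in universe], dtype=np.int64)


def auprc_ratio(
    scores, truth: GroundTruthNetwork, scored_genes
) -> EvaluationResult:
    """Average-precision AUPRC over the candidate universe, over density.

    Also computes early precision at k = number of true edges in the
    universe, so a single call returns all four metric fields.
    """
    universe = evaluation_universe(scored_genes, truth)
    y = _truth_labels(truth, universe)
    n_true = int(y.sum())
    if n_true == 0:
        raise ValueError("ground truth shares no edges with the candidate universe")
    s = _ranked_scores(scores, universe)
    density = n_true / len(universe)
    auprc = float(average_precision_score(y, s))
    early = _early_precision(s, y, universe, n_true)
    return EvaluationResult(
        auprc=auprc,
        auprc_ratio=auprc / density,
        early_precision=early,
        epr=early / density,
        candidate_count=len(universe),
        truth_count=n_true,
    )


def _early_precision(
    s: np.ndarray, y: np.ndarray, universe: list[tuple[str, str]], k: int
) -> float:
    # ties broken by lexicographic pair id for determinism
    order = sorted(range(len(universe)), key=lambda i: (-s[i], universe[i]))
    top = order[:k]
    return float(y[top].sum()) / k


def epr(scores, truth: GroundTruthNetwork, scored_genes, k: int | None = None) -> float:
    """Early precision ratio at cutoff k (default: number of true edges)."""
    universe = evaluation_universe(scored_genes, truth)
    y = _truth_labels(truth, universe)
    n_true = int(y.sum())
    if n_true == 0:
        raise ValueError("ground truth shares no edges with the candidate universe")
    if k is None:
        k = n_true
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(universe):
        raise ValueError(f"k={k} exceeds universe size {len(universe)}")
    s = _ranked_scores(scores, universe)
    density = n_true / len(universe)
    return _early_precision(s, y, universe, k) / density


def evaluate_grn(
    grn: InferredGRN, truth: GroundTruthNetwork, scored_genes
) -> EvaluationResult:
    """Convenience wrapper evaluating an inferred network end to end."""
    return auprc_ratio(grn, truth, scored_genes)


# ---------------------------------------------------------------------------
# robustness perturbations
# ---------------------------------------------------------------------------

def remove_prior_edges(
    prior: PriorNetwork, fraction: float, seed: int
) -> PriorNetwork:
    """Remove exactly round(fraction * |E|) edges uniformly; nodes unchanged."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(prior.edges)
    n_remove = int(round(fraction * len(edges)))
    drop = set(rng.choice(len(edges), size=n_remove, replace=False).tolist())
    kept = {e for i, e in enumerate(edges) if i not in drop}
    return prior.with_edges(kept)


def downsample_cells(
    X: GeneExpressionMatrix, fraction: float, seed: int
) -> GeneExpressionMatrix:
    """Remove exactly round(fraction * d) cell columns uniformly."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    d = X.n_cells
    n_remove = int(round(fraction * d))
    drop = set(rng.choice(d, size=n_remove, replace=False).tolist())
    keep = [j for j in range(d) if j not in drop]
    return GeneExpressionMatrix(
        X.values[:, keep],
        list(X.gene_ids),
        [X.cell_ids[j] for j in keep],
        normalized=X.normalized,
    )


def corrupt_prior(
    prior: PriorNetwork,
    fraction: float,
    mode: str = "random-swap",
    seed: int = 0,
    max_attempts_factor: int = 100,
) -> PriorNetwork:
    """Replace a fraction of prior edges with false edges; |E| is conserved.

    ``random-swap`` deletes round(fraction * |E|) edges and adds the same
    number of uniformly drawn non-edges.  ``degree-preserving-swap``
    repeatedly rewires edge pairs (a->b, c->d) -> (a->d, c->b), rejecting
    self-loops and duplicates, until the target fraction of original edges
    has been displaced; the in/out degree sequences are invariant.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    original = sorted(prior.edges)
    n_edges = len(original)
    n_target = int(round(fraction * n_edges))
    if n_target == 0:
        return prior.with_edges(set(original))

    if mode == "random-swap":
        drop_idx = set(rng.choice(n_edges, size=n_target, replace=False).tolist())
        kept = {e for i, e in enumerate(original) if i not in drop_idx}
        current = set(kept)
        n = prior.n_genes
        while len(current) < n_edges:
            i = int(rng.integers(n))
            j = int(rng.integers(n))
            if i != j and (i, j) not in current and (i, j) not in prior.edges:
                current.add((i, j))
        return prior.with_edges(current)

    if mode == "degree-preserving-swap":
        current = list(original)
        original_set = set(original)
        max_attempts = max_attempts_factor * n_edges
        attempts = 0
        while attempts < max_attempts:
            displaced = sum(1 for e in current if e not in original_set)
            if displaced >= n_target:
                break
            attempts += 1
            ia, ic = rng.integers(len(current), size=2)
            if ia == ic:
                continue
            a, b = current[ia]
            c, d = current[ic]
            new1, new2 = (a, d), (c, b)
            if a == d or c == b:
                continue
            cur_set = set(current)
            if new1 in cur_set or new2 in cur_set:
                continue
            current[ia] = new1
            current[ic] = new2
        displaced = sum(1 for e in current if e not in set(original))
        if displaced < n_target:
            warnings.warn(
                f"degree-preserving swap reached {displaced}/{n_target} "
                f"displaced edges after {max_attempts} attempts"
            )
        return prior.with_edges(set(current))

    raise ValueError(f"unknown corruption mode: {mode!r}")


def random_prior_baseline(
    prior: PriorNetwork, tf_set, h: int, seed: int
) -> InferredGRN:
    """Baseline: H edges sampled uniformly from prior edges with TF sources."""
    rng = np.random.default_rng(seed)
    tfs = set(tf_set)
    candidates = sorted(
        (prior.gene_ids[i], prior.gene_ids[j])
        for i, j in prior.edges
        if prior.gene_ids[i] in tfs
    )
    if not candidates:
        raise ValueError("prior network has no edges with TF sources")
    h = min(h, len(candidates))
    pick = rng.choice(len(candidates), size=h, replace=False)
    scores = rng.random(h)
    order = np.argsort(-scores, kind="stable")
    records = [
        (candidates[pick[i]][0], candidates[pick[i]][1], scores[i])
        for i in order
    ]
    df = pd.DataFrame(records, columns=["tf", "target", "score"])
    df["rank"] = np.arange(1, len(df) + 1)
    return InferredGRN(df, tfs & {a for a, _ in candidates}, seed)
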