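"""Synthetic benchmark cases with the statistical structure the method
assumes: a scale-free directed prior network, a planted "true" sub-GRN
whose overlap with the prior is controllable, and an expression matrix
driven by the planted GRN.

The expression model is deliberately simple: per cell, each TF draws a
lognormal activity; each regulated gene is a softplus of the signed
weighted sum of its regulators' activities plus Gaussian noise; entries
are then zeroed by Bernoulli dropout.  This creates recoverable
regulator-target covariation without a kinetic simulator, and the dropout
emulates the zero inflation typical of single-cell counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    GeneExpressionMatrix,
    GroundTruthNetwork,
    PriorNetwork,
)

__all__ = [
    "SyntheticCase",
    "simulate_prior",
    "plant_truth",
    "simulate_expression",
    "make_benchmark_case",
    "write_case",
    "PROFILES",
]

# profile: (n_genes, n_tfs, n_cells, m_attach, n_true_edges)
PROFILES: dict[str, tuple[int, int, int, int, int]] = {
    "tiny": (30, 5, 50, 2, 25),
    "small": (150, 20, 300, 3, 150),
    "default": (600, 60, 800, 3, 600),
}


@dataclass
class SyntheticCase:
    expression: GeneExpressionMatrix   # raw (un-normalized)
    prior: PriorNetwork
    truth: GroundTruthNetwork
    tf_set: set[str]
    params: dict = field(default_factory=dict)


def _gene_names(n_genes: int, n_tfs: int) -> list[str]:
    width = len(str(n_genes))
    names = [f"TF{i + 1:0{width}d}" for i in range(n_tfs)]
    names += [f"G{i + 1:0{width}d}" for i in range(n_genes - n_tfs)]
    return names


def simulate_prior(
    n_genes: int,
    n_tfs: int,
    m_attach: int = 3,
    seed: int = 0,
    forward_prob: float = 0.7,
) -> tuple[PriorNetwork, set[str]]:
    """Directed preferential-attachment prior with the oldest nodes as TFs.

    Growth starts from a small connected core; each new node attaches
    ``m_attach`` edges to existing nodes chosen with probability
    proportional to current degree.  An edge to a TF partner always points
    TF -> new (regulators acquire targets); otherwise it points old -> new
    with probability ``forward_prob``, else new -> old.  The early,
    high-degree nodes are labeled TFs, mirroring the hub role regulators
    play in real networks.
    """
    if m_attach >= n_genes:
        raise ValueError("m_attach must be smaller than n_genes")
    if n_tfs >= n_genes or n_tfs < 1:
        raise ValueError("need 1 <= n_tfs < n_genes")
    rng = np.random.default_rng(seed)
    core = m_attach + 1
    edges: set[tuple[int, int]] = set()
    degree = np.zeros(n_genes, dtype=np.float64)
    for v in range(1, core):  # small connected seed core
        edges.add((v - 1, v))
        degree[v - 1] += 1
        degree[v] += 1
    for new in range(core, n_genes):
        weights = degree[:new] + 1.0
        probs = weights / weights.sum()
        partners: set[int] = set()
        while len(partners) < m_attach:
            partners.add(int(rng.choice(new, p=probs)))
        for old in sorted(partners):
            if old < n_tfs or rng.random() < forward_prob:
                edge = (old, new)
            else:
                edge = (new, old)
            edges.add(edge)
            degree[old] += 1
            degree[new] += 1
    names = _gene_names(n_genes, n_tfs)
    prior = PriorNetwork(names, edges)
    tf_set = set(names[:n_tfs])
    return prior, tf_set


def plant_truth(
    prior: PriorNetwork,
    tf_set,
    n_true_edges: int,
    prior_overlap_fraction: float = 0.8,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Sample the true GRN with a controlled overlap with the prior.

    round(overlap * n_true) edges come from prior edges with TF sources;
    the remainder from TF x gene pairs outside the prior.
    """
    if not 0 <= prior_overlap_fraction <= 1:
        raise ValueError("prior_overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tfs = sorted(set(tf_set) & set(prior.gene_ids))
    prior_names = prior.edge_names()
    in_prior = sorted((a, b) for a, b in prior_names if a in set(tfs))
    out_prior = sorted(
        (a, b)
        for a in tfs
        for b in prior.gene_ids
        if a != b and (a, b) not in prior_names
    )
    n_in = int(round(prior_overlap_fraction * n_true_edges))
    n_out = n_true_edges - n_in
    if n_in > len(in_prior):
        raise ValueError(
            f"requested {n_in} prior-overlapping true edges but only "
            f"{len(in_prior)} prior edges have TF sources"
        )
    if n_out > len(out_prior):
        raise ValueError("not enough non-prior TF-gene pairs for the truth")
    pick_in = rng.choice(len(in_prior), size=n_in, replace=False)
    pick_out = rng.choice(len(out_prior), size=n_out, replace=False)
    edges = {in_prior[i] for i in pick_in} | {out_prior[i] for i in pick_out}
    return GroundTruthNetwork(edges, set(tfs))


def simulate_expression(
    truth: GroundTruthNetwork,
    tf_set,
    gene_ids,
    n_cells: int,
    noise_sd: float = 0.3,
    dropout_rate: float = 0.2,
    seed: int = 0,
) -> GeneExpressionMatrix:
    """Expression driven by the planted GRN.

    Unregulated TFs draw lognormal(0, 1) activities per cell.  Signal
    propagates through the truth network in dependency order: a regulated
    gene's signal is softplus(sum of signed weights x its regulators'
    signals), with edge weights of magnitude U(0.5, 1.5) and random sign,
    so a regulated TF drives its own targets with the same values a
    measurement would see.  Cycles fall back to an intrinsic lognormal
    activity for the not-yet-resolved regulator.  Gaussian noise
    (clipped at zero) and Bernoulli dropout are applied afterwards as
    observation-level effects and do not propagate.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    tfs = sorted(set(tf_set) & set(gene_ids))
    n = len(gene_ids)

    regulators: dict[str, list[tuple[str, float]]] = {}
    for a, b in sorted(truth.edges):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        regulators.setdefault(b, []).append((a, sign * rng.uniform(0.5, 1.5)))

    intrinsic = {tf: rng.lognormal(0.0, 1.0, size=n_cells) for tf in tfs}
    signal: dict[str, np.ndarray] = {}

    def resolve(g: str, stack: set[str]) -> np.ndarray:
        if g in signal:
            return signal[g]
        if g in stack or g not in regulators:  # cycle break or source node
            return intrinsic.setdefault(g, rng.lognormal(0.0, 1.0, size=n_cells))
        stack.add(g)
        drive = np.zeros(n_cells)
        for reg, w in regulators[g]:
            drive += w * resolve(reg, stack)
        stack.discard(g)
        signal[g] = np.logaddexp(0.0, drive)  # softplus, numerically safe
        return signal[g]

    values = np.zeros((n, n_cells))
    for g in gene_ids:
        base = resolve(g, set())
        if noise_sd > 0:
            base = base + rng.normal(0.0, noise_sd, size=n_cells)
        values[index[g]] = np.maximum(base, 0.0)
    if dropout_rate > 0:
        keep = rng.random(values.shape) >= dropout_rate
        values = values * keep
    cells = [f"cell{j + 1:04d}" for j in range(n_cells)]
    return GeneExpressionMatrix(values, gene_ids, cells, normalized=False)


def make_benchmark_case(
    profile: str = "small",
    seed: int = 0,
    prior_overlap_fraction: float = 0.8,
    noise_sd: float = 0.3,
    dropout_rate: float = 0.2,
) -> SyntheticCase:
    """Self-consistent prior + truth + expression for a named size profile.

    Profiles: tiny (30 genes / 5 TFs / 50 cells), small (150 / 20 / 300),
    default (600 / 60 / 800).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    n_genes, n_tfs, n_cells, m_attach, n_true = PROFILES[profile]
    prior, tf_set = simulate_prior(n_genes, n_tfs, m_attach, seed)
    truth = plant_truth(prior, tf_set, n_true, prior_overlap_fraction, seed + 1)
    expression = simulate_expression(
        truth, tf_set, prior.gene_ids, n_cells, noise_sd, dropout_rate, seed + 2
    )
    params = {
        "profile": profile,
        "seed": seed,
        "n_genes": n_genes,
        "n_tfs": n_tfs,
        "n_cells": n_cells,
        "m_attach": m_attach,
        "n_true_edges": n_true,
        "prior_overlap_fraction": prior_overlap_fraction,
        "noise_sd": noise_sd,
        "dropout_rate": dropout_rate,
    }
    return SyntheticCase(expression, prior, truth, tf_set, params)


def write_case(case: SyntheticCase, outdir) -> dict[str, Path]:
    """Write expression TSV, prior TSV, TF list, truth TSV and params JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "prior": outdir / "prior.tsv",
        "tfs": outdir / "tfs.txt",
        "truth": outdir / "truth.tsv",
        "params": outdir / "params.json",
    }
    df = pd.DataFrame(
        case.expression.values,
        index=case.expression.gene_ids,
        columns=case.expression.cell_ids,
    )
    df.to_csv(paths["expression"], sep="\t")
    with open(paths["prior"], "w") as fh:
        for a, b in sorted(case.prior.edge_names()):
            fh.write(f"{a}\t{b}\t1.0\n")
    with open(paths["tfs"], "w") as fh:
        fh.writelines(f"{tf}\n" for tf in sorted(case.tf_set))
    with open(paths["truth"], "w") as fh:
        for a, b in sorted(case.truth.edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["params"], "w") as fh:
        json.dump(case.params, fh, indent=2)
    return paths
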