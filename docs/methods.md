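# Methods

## Model

`reggain` infers a directed TF → target network for one cell population
from two inputs: a genes × cells expression matrix and a directed prior
gene-interaction network. The prior is used as a structural scaffold, not
as training labels: a self-supervised contrastive objective learns gene
embeddings that are stable under stochastic corruption of the prior
graph, and the network is then read out from embedding similarities with
a multiplicative bonus for prior-supported pairs.

The central modelling commitments are:

* **Dual roles.** Regulation is asymmetric, so each gene carries two
  embeddings learned by two independent encoders: f_out on the adjacency
  A aggregates a gene's targets (its regulator-driven pattern), f_in on
  Aᵀ aggregates its regulators (its target-driven pattern). Aᵀ is
  normalized *after* transposition — for directed graphs
  normalize(Aᵀ) ≠ normalize(A)ᵀ, and this order treats both roles
  identically.
* **High-order convolution.** Each layer aggregates neighborhood orders
  S = {0, 1, 2} simultaneously, one trainable weight matrix per order,
  with per-order tanh applied before column-wise concatenation. Powers of
  the normalized adjacency are computed once per view per epoch and
  shared across layers. Layers are bias-free, which keeps the invariant
  that a zero feature matrix encodes to zero.
* **Topology-aware augmentation.** Scale-free graphs are robust to
  uniform edge removal, so one of the two views corrupts the hub
  subgraph (top 15 % of genes by total degree; edges with both endpoints
  in that set) at elevated rates. Feature masking is row-level — a
  selected gene's whole expression vector is zeroed — because the view-2
  group-specific masking probabilities are defined per node, and a
  mixed per-entry interpretation would not respect them.
* **Fresh views per epoch.** Both views are regenerated every epoch from
  a per-epoch, per-view seed (`base·10⁶ + 4·epoch + view`), which
  increases augmentation diversity and keeps every draw replayable.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α₁, α₂, α₃ | 0.3, 0.6, 0.3 | edge-drop rates: view 1; hub edges (Es); other edges (Er) |
| β₁, β₂, β₃ | 0.2, 0.5, 0.2 | feature-mask rates: view 1; hub genes (Vs); other genes (Vr) |
| hub fraction | 0.15 | floor(0.15·N) highest-total-degree genes form Vs (ties: lexicographic id) |
| layer widths | [80,80,10]/[40,40,5]/[16,16,2] | per-order output widths; final embedding 34-dim |
| τ | 3 | contrastive temperature on cosine similarities |
| epochs / lr | 500 / 0.001 | Adam, full batch, no scheduling or early stopping |
| γ | 10 | prior-edge multiplier in the score matrix; γ = 1 disables the prior (recommended for differential-regulation analyses) |
| runs | 10 | independent trainings whose score matrices are averaged (seeds base+0 … base+r−1) |
| H | 10 × N | edges kept in the final network, ranked by averaged score |
| normalization scale | 10⁴ | per-gene total-count scaling before log1p; cancels in cosines |

Normalization is applied before gene selection. Gene selection keeps all
nonzero-variance TFs plus the top-N most variable genes. Degree
centrality is raw total degree (in + out) on the directed prior.
Duplicate directed edges collapse; antiparallel pairs are kept as two
edges; self-loops are dropped everywhere, and self-pairs are excluded
from both the score ranking and the evaluation universe.

## Compute engine

The encoders, projection heads and loss are differentiated by a small
reverse-mode tape over dense float64 numpy arrays (`reggain._autodiff`),
with Adam implemented alongside. Networks of this size (three layers,
widths ≤ 170, full-graph batches) need nothing heavier; gradient
correctness is enforced in the test suite by central finite-difference
checks on the full encoder-plus-loss composition. Determinism is
promised at fixed seed on a fixed platform/thread configuration.

## Evaluation

Metrics are computed over a fixed candidate universe: (TFs present in
the ground truth) × (genes in the scored set), minus self-pairs.
Candidates the method never scored are placed below every scored
candidate, so missing edges are penalized rather than silently dropped.
AUPRC uses average precision (step-wise, ties grouped — the same
variant as `sklearn.metrics.average_precision_score`); early precision
uses k = number of ground-truth edges in the universe with
deterministic lexicographic tie-breaking. Both are divided by the
ground-truth density in the universe, the expected value of a random
predictor, so 1.0 means random. Robustness perturbations use exact
without-replacement sampling (round(f·|E|) edges, round(f·d) cells) so
the nominal levels are exact; degree-preserving corruption uses
double-edge swaps that leave both degree sequences bit-identical and
falls back with a warning if the target displacement cannot be reached.

## Synthetic benchmark

The generator produces the statistical structure the method assumes, at
desk scale:

* **Prior**: directed preferential attachment; each new gene attaches
  m edges (tiny/small/default profiles: m = 2/3/3) to existing genes
  with probability proportional to degree. Edges whose older endpoint is
  a TF point TF → new (regulators acquire targets); otherwise old → new
  with probability 0.7. The earliest, highest-degree genes are the TFs.
  This yields a heavy-tailed degree distribution with TF hubs.
* **Truth**: n_true edges (25/150/600 for the three profiles) with a
  controllable fraction (default 0.8) drawn from prior edges with TF
  sources and the rest from TF × gene pairs outside the prior.
* **Expression**: unregulated TFs draw lognormal(0, 1) activity per
  cell; signal propagates through the truth network in dependency order
  — a regulated gene is softplus(Σ ±U(0.5, 1.5) · regulator signal) —
  so a regulated TF drives its targets with the same values a
  measurement would see (cycles fall back to intrinsic activity).
  Gaussian noise (σ = 0.3, clipped at zero) and Bernoulli dropout
  (rate 0.2) are applied afterwards as observation-level effects.

Profiles: tiny = 30 genes / 5 TFs / 50 cells (unit tests), small =
150 / 20 / 300 (integration and acceptance), default = 600 / 60 / 800.
The acceptance runs use the small profile with 100 epochs and 3 averaged
runs, sizes chosen so the whole pipeline re-runs in seconds on one CPU.

What the generator does *not* emulate: count statistics (expression is
continuous, not negative-binomial counts), cell subpopulations or
trajectories, batch effects, signed/repressive edge recovery, or the
scale of real priors and transcriptomes. Passing the synthetic recovery
checks shows the pipeline concentrates planted regulator→target signal
far above random under its own assumptions; it does not certify
performance on real single-cell data.

## Known limitations

* **Cross-role alignment is unconstrained.** The loss compares
  embeddings within each role only; nothing couples f_out to f_in. The
  regulatory score — a cosine *between* the two spaces — therefore has
  an arbitrary global alignment component per training run. Averaging
  over runs damps the variance but not a run's overall sign; on very
  small graphs (the tiny profile) whole runs can anti-align, which is
  why quantitative benchmarks use the small profile and 3–10 averaged
  runs.
* **Multiplicative prior emphasis de-emphasizes negative scores.**
  P multiplies signed cosines, so a prior edge whose cosine falls below
  1/γ ranks *below* non-prior pairs with higher raw cosine — for those
  edges the intended emphasis inverts. When the ground truth lies mostly
  inside a small prior this costs measurable average precision against a
  baseline that simply keeps every prior edge on top; the acceptance
  script reports both the pipeline's metrics and that random-prior
  baseline side by side rather than hiding the comparison.
* Only positive regulatory potential is scored; activation vs repression
  is not distinguished. One network is inferred per input matrix.
* The Wilcoxon differential-edge test defaults to unadjusted p < 0.05
  per edge (a Benjamini–Hochberg mode is available); the edge universe
  for differential testing is the union of each sample's top-H edges.
* The motif hit-ratio analysis consumes a precomputed (TF, gene, hit)
  table; the upstream scan (FIMO at p < 1e-4 over ±200 kb TSS windows
  with JASPAR motifs, or equivalent) is out of scope and its parameters
  belong to that tool's invocation.

## Design decisions taken where the design was open

* Embedding normalization for scoring is row-wise L2 (making M entries
  cosines in [−1, 1]), matching the cosine-based training similarity.
* The 1/(2N) averaging of the total loss is kept literally; it scales
  the loss, not the optimum.
* Each role has its own projection head; the loss never compares across
  roles, so sharing would couple the roles for no modelled reason.
* Weight initialization is Glorot-uniform from the run seed.
* Top-H selection ranks the TF × gene universe (not all N × N pairs),
  since only TF-source edges are reported.
* k-means/Leiden clustering standardizes embedding dimensions first;
  Leiden runs on a k = 15 nearest-neighbor graph.
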