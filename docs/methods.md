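# Methods

## Problem and model

`netortho` treats cross-species ortholog detection as binary classification
of sequence-homologous gene/protein pairs. The working assumption is that a
true ortholog pair preserves not only sequence similarity but also network
context: its interaction (or coexpression) neighborhoods in the two species
should contain homologous partners at similar topological positions.
Sequence similarity proposes candidates; network similarity ranks them.

Inputs are two undirected graphs — unweighted PPI edge lists, or
coexpression graphs built here from genes × tissues expression matrices —
a bidirectional BLAST score table, and curated ortholog labels. The
candidate universe is exactly the set of BLAST-matched pairs passing the
e-value filter; pairs without detectable sequence homology are never scored.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| e-value cutoff | 1e-10 | BLAST rows above this are discarded |
| correlation cutoff | 0.8 | minimum \|Spearman ρ\| for a coexpression edge |
| λ (walk damping) | 0.01 | geometric down-weighting of long random walks |
| k (hop radii) | 1 and 2 | neighborhood sizes compared by the kernels |
| ε (length tolerance) | 0 unit / 0.05 weighted | shortest-path length agreement |
| folds | 10 | stratified cross-validation folds |

**Coexpression networks.** Probe rows are mapped to genes and averaged
(arithmetic mean) to one value per gene per tissue; pairwise Spearman
correlations (average ranks for ties) are thresholded at |ρ| ≥ 0.8, and the
edge weight is |ρ|. Sign is discarded after thresholding: the kernels and
distances need a coupling magnitude, and the cutoff rule itself is on the
absolute value. Genes with constant expression have undefined ρ; they are
excluded from pairing but kept as isolated nodes so node counts stay
predictable.

**Homology map.** Bit scores (not −log e-values) are averaged across the
two BLAST directions; one-sided hits keep their single score. Inside the
kernels the averaged scores are min–max normalized to [0, 1] over all pairs
in the map, so kernel magnitudes do not depend on the bit-score scale. Note
one consequence: the weakest pair in the map normalizes to 0 and contributes
nothing to kernel sums.

**Kernels.** Hop counting is topological even on weighted graphs; weights
enter only through edge *lengths* 1 − |ρ| (high correlation = short
distance; the alternative 1/|ρ| was rejected for unbounded lengths) and the
random-walk coupling w_C·w_Z. The shortest-path kernel sums
hom(u,u′)·hom(v,v′) over ordered cross-pairs whose Floyd–Warshall path
lengths agree within ε (ε = 0 on unit-length graphs, where lengths are
integers; 0.05 on weighted graphs, where exact equality would almost never
fire). The soft product form w_C·w_Z for the random-walk coupling keeps K
linear-algebraic; a hard gate (match iff |w_C − w_Z| ≤ τ) is available via
the `rw_weight_gate` config knob.

The random-walk kernel is defined as p (I − λK)⁻¹ q on the nm × nm
homology-weighted Kronecker-product matrix. Because every row and column of
K indexed by a vertex pair with zero homology vanishes, K is block-diagonal,
and the computation reduces exactly to the (usually tiny) homology-supported
block: k_rw = (nm − |S|) + 1ᵀ(I − λK_SS)⁻¹1. The test suite verifies this
against a truncated Neumann series on the explicit full matrix. Convergence
requires λ·ρ(K) < 1 and is checked with a dense eigenvalue computation on
the supported block; violation raises an error naming the spectral radius.
Degenerate cases: an edgeless or homology-free neighborhood pair returns
n·m (the identity inverse), so an isolated candidate pair has RW = 1 and
SP = 0.

**Centralities and pair normalization.** BaryCenter (sum of shortest-path
distances, smaller = central, isolated nodes 0), betweenness (unordered
source–target pairs, fractional path counts), degree, and HITS are computed
on the *whole* graph — centrality is a node property, and each candidate
pair receives one value per measure. Weighted variants reuse the 1 − |ρ|
edge length for consistency with the kernels. HITS is an explicit power
iteration with L2 normalization (tolerance 1e-8, cap 1000 iterations); on
undirected graphs hubs and authorities coincide, so the score is twice the
dominant adjacency eigenvector entry. On bipartite graphs that eigenspace
is degenerate (the classic HITS ambiguity); the iteration still converges
from its uniform start, but eigensolver comparisons are only meaningful on
non-bipartite graphs, which is how the tests are scoped. Per-pair scores
are 1 − |ŝ_x − ŝ_y| on within-graph min–max-normalized values; a graph
whose scores are all equal normalizes to 0. BaryCenter is left in its raw
orientation (smaller = central) since the absolute-difference form makes
orientation immaterial.

**Classification.** "Decision tree" is realized as AdaBoost over depth-3
trees (50 rounds); the SVM is an RBF SVC wrapped in Platt-sigmoid
calibration (internal 3-fold CV) so its probabilities can be averaged; the
ensemble is the unweighted mean of the four members' probabilities —
chosen for determinism and transparency. Features are z-scored inside the
model pipeline, so cross-validation standardizes with training-fold
statistics only. AUC uses the Mann–Whitney formulation (ties count half)
on pooled out-of-fold scores and is reported in percent. Average ranks are
computed per dataset by descending AUC with ties averaged, then averaged
across datasets. Classifier hyperparameters are recorded in each saved
model's JSON metadata.

**RBH baseline.** (a, b) is predicted iff each is the other's top averaged
score. Score ties are broken toward the lexicographically smallest ID and
flagged, which guarantees the prediction set is a partial matching. When
the baseline is evaluated by AUC, its binary predictions are the scores
(ties counting half).

## Reconstructed formulas

Two formulas in the source material for this method family are not printed
in recoverable form, and the implementations here are deliberate
reconstructions satisfying the stated properties rather than verbatim
transcriptions:

- the shortest-path kernel summand — implemented as the standard
  walk-length-comparison kernel with homology-weighted vertex matching and
  the κ_len tolerance described above;
- the centrality pair-combination formula — implemented as min–max
  normalization within each graph followed by 1 − |difference|, which is
  normalized per pair and insensitive to the two graphs' score magnitudes.

## Synthetic data: what it emulates, what it does not

`generate_network_pair` defaults (n = 100 nodes, edge probability 0.08,
rewire rate 0.1, ortholog fraction 0.5, decoy rate 0.1) give two ~8-degree
networks whose correspondence is progressively hidden as the rewire rate
grows. Ortholog pairs draw homology scores from Normal(500, 50) and decoys
from Normal(150, 50), both truncated at 1 and split into two jittered
BLAST directions; decoy count is the deterministic round(rate·n) so
stratified 10-fold CV always has enough negatives. Scores in the hundreds
keep the blast feature on a realistic bit-score scale. Erdős–Rényi topology
was chosen for analytic transparency; `model="preferential_attachment"`
provides heavy-tailed degree distributions closer to real interactomes.

`generate_expression_pair` defaults (50 genes, 13 tissues — a typical
multi-tissue panel size — 5 modules, noise SD 0.25) make within-module
correlations comfortably exceed the 0.8 cutoff while between-module pairs
stay below it; orthologous genes share latent profiles across species.

Limitations to keep in mind when reading test results:

- The synthetic ortholog and decoy bit-score distributions barely overlap,
  so on this data the blast feature alone is essentially perfectly
  separating and classifiers saturate near AUC 100 with or without network
  features. Passing tests therefore demonstrate correctness of every
  stage, and that kernel features alone carry recoverable signal that
  degrades with rewiring — not that network features improve on an
  already-perfect sequence baseline. Real data, where paralogs and domain
  sharing give non-orthologs high BLAST scores, is precisely where the
  network features have room to help; emulating that confusability is out
  of scope for this generator.
- Rewiring is independent per edge; real interactome divergence is
  correlated with gene duplication and study bias.
- Expression noise is i.i.d. Gaussian on a shared latent profile; no
  platform effects, missing tissues, or probe cross-hybridization.

## Problem sizes

Tests and the acceptance script run at the default study conditions: 10
replicate instances of 100 nodes (~60 candidate pairs each), kernel oracle
comparisons on hundreds of random neighborhood pairs of ≤ 8 nodes,
distance and betweenness oracles on graphs of ≤ 15 nodes, and RBH oracles
on 1000 random tables. These sizes keep every oracle exhaustive while
exercising the same code paths used at scale.
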