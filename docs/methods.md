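# Methods

## Problem and model

Spatial transcriptomics assays measure a counts matrix **X** (N spots ×
G genes) together with planar coordinates **Y** (N × 2). A *spatial
domain* is a spatially contiguous tissue region with a consistent
expression program — distinct from a cell type, whose members may be
scattered. The package identifies domains in three stages.

### 1. Expression features from a count-model autoencoder

Raw counts are library-size normalized and log1p-transformed to X̃
(target sum = median library size by default; the transform keeps zeros
at zero). An autoencoder with two ReLU encoder layers (G → m′ → m,
m′ = 128, m = 32) compresses X̃ into the expression embedding **Z**. The
decoder expands Z back to m′ and emits the parameters of a negative
binomial (NB) or zero-inflated negative binomial (ZINB) observation
model for the *raw* counts:

    NB(x; r, p)   = Γ(x+r) / (x! Γ(r)) · p^r (1−p)^x          (mean r(1−p)/p)
    ZINB(x; π, r, p) = π δ₀(x) + (1−π) NB(x; r, p)

with per-entry dispersion R = exp(·), per-entry zero-inflation
Π = sigmoid(·), and a per-gene success probability p_g = sigmoid(θ_g)
from a free logit vector (p is shared across spots within a gene, so it
is a gene-level parameter rather than a decoder output head). The loss
is the mean negative log-likelihood over all N×G entries; mean (not
sum) reduction keeps the learning rate meaningful across dataset sizes.
Training is full-batch Adam, learning rate 1e-3, 40 iterations, dropout
0.1 after each encoder activation (off at inference). ZINB is the
default for highly sparse platforms (Stereo-seq, Slide-seqV2), NB for
denser ones (STARmap, Visium); `family="auto"` chooses ZINB above 90%
zeros.

Numerical notes: the ZINB at-zero term is computed by log-sum-exp of
{log π, log(1−π) + r log p} so it stays finite at ~98% sparsity; p is
clipped to [1e-8, 1−1e-8] inside the likelihood for gradient stability;
π = 0 and π = 1 are honored exactly in the numpy evaluation path (π = 1
yields log-probability −inf at positive counts). Because most entries
are zero and the NB log-pmf collapses to r log p at x = 0, the training
path evaluates the Γ-function terms only on nonzero entries — values
and gradients are identical to the dense formula.

The model trains on a small in-repo reverse-mode autodiff engine over
numpy (`sece._autograd`); its gradients are validated against central
finite differences in the test suite.

### 2. Spatial structure: local adjacency and global similarity

Two views of the coordinates are built:

* **ADM** — binary symmetric k-nearest-neighbor adjacency (OR
  symmetrized, self excluded; k = 6 on the hexagonal Visium lattice,
  10 elsewhere). Exact-distance ties break by spot index.
* **SSM** — Gaussian similarity Σ_ij = exp(−‖y_i − y_j‖² / (2γ)).
  The bandwidth γ defaults to the 0.05 quantile of pairwise *squared*
  distances, which shares units with the numerator and therefore makes
  Σ invariant to uniform coordinate rescaling — native platform units
  never matter. Both readings of the kernel constant and of the
  quantile are exposed (`kernel_halving`, `gamma_on`) for sensitivity
  analysis. Above 20,000 spots the quantile is estimated from a seeded
  10,000-spot subsample.

### 3. Spatial embedding from graph attention

Two graph-attention layers (both width 32, single head) aggregate each
spot's neighborhood — self-loop included, since the reconstruction
target below is unreachable for a node that cannot see its own
features. Attention scores e_ij = aᵀ[Wh_i ∥ Wh_j] are softmax-normalized
over each target's aggregation set and evaluated only on graph edges
(edge-list softmax + sparse aggregation; the adjacency has ~k·N of N²
entries). ELU is applied inside layer 1; layer 2 is linear by default so
the embedding is unconstrained in sign (`final_activation` switches ELU
back on).

Training minimizes

    loss = λ_global · MSE(UUᵀ, Σ) + λ_local · MSE(U, Z)

over all N² Gram entries (diagonal included) and all N·m feature
entries, full-batch Adam, learning rate 1e-2, 50 iterations, dropout
0.2 on input features and attention coefficients. λ_local = 1 always;
λ_global follows the platform presets 0.08 (Stereo-seq, Slide-seqV2),
0.3 (Visium), 2 (STARmap) — smaller for larger, higher-resolution
fields of view. The global term is evaluated blockwise over row blocks
of UUᵀ against lazily computed Σ rows, so the dense N×N similarity never
needs to be materialized; blockwise and dense evaluation are
mathematically identical (gradient (4/N²)(UUᵀ−Σ)U, valid because Σ is
symmetric).

Three conditioning choices make the short 50-iteration schedule
converge to a good embedding; all are deterministic given the seed:

* **Z is divided by its mean row norm** before entering the GAT. The
  local objective pulls ‖U‖ toward ‖Z‖ while the Gram objective needs
  unit-scale rows (Σ ∈ (0, 1]); with raw Z the optimizer spends its
  budget walking the scale rather than shaping geometry, and lands
  mid-transition. With unit-scale Z both objectives agree on scale.
* **Attention vectors initialize at zero**, so the first pass is plain
  neighborhood averaging — a well-behaved smoother — and the attention
  asymmetry is learned from there.
* **The output layer is rescaled once** so the initial U has unit mean
  row norm, matching the Gram target from step one.

### 4. Clustering and metrics

The embedding U is clustered with an EM-fit Gaussian mixture at a
user-supplied number of domains (from an annotation or atlas; no
automatic model selection). The default covariance structure is a
single full covariance shared by all components ("shared-full", the
equal-ellipsoid model traditional in this literature); per-cluster-full
and diagonal are selectable. Initialization is k-means (k-means++
seeding plus Lloyd refinement), best of 10 seeded starts by final
log-likelihood; bare k-means++ seeding without refinement left EM in
poor local optima on 32-dimensional embeddings. Degenerate EM runs are
retried with re-seeding and growing covariance regularization, bounded
at three attempts.

Evaluation metrics:

* **ARI** — adjusted Rand index from the contingency table with pair
  counts C(n, 2); range [−1, 1].
* **ACC** — accuracy after the optimal one-to-one relabeling of
  predictions, solved as an assignment problem on the (zero-padded
  square) contingency table via the Kuhn–Munkres algorithm. Note the
  bound ACC ≥ (largest class)/N holds for a constant predictor, not for
  arbitrary predictions.
* **ASW** — mean silhouette width of the embedding under given labels,
  Euclidean distance; singleton clusters contribute 0.
* **LISI** — per-spot local inverse Simpson index over the
  `neighborhood_size = 30` spatial nearest neighbors (self included):
  1 / Σ_l p(l)². The naive reciprocal of summed probabilities is
  identically one, so the inverse *Simpson* form is the meaningful
  quantity; both the raw index (range [1, |L|], smaller = stronger
  aggregation) and the |L|-normalized variant (range (0, 1]) are
  available, with the normalized form as the default reported value.

## Synthetic fixtures

The generator emulates layered or ring-shaped tissue with
domain-specific (ZI)NB expression programs: per-gene baseline log-means
are normal with spread `gene_logmean_sd` (log-normal abundance tail),
each domain's program up-regulates a 10% marker block by `effect_size`
log units, relative expression is the softmax of the log-means,
per-spot means scale by a log-uniform library size, and counts are NB
with dispersion r, optionally zeroed with probability π. Ring geometry
lays spots on a disk (radius bands on a square support would degenerate
into corner patches). Three presets mimic platform regimes at desk
scale:

| preset | spots | genes | domains | family | zeros |
|---|---|---|---|---|---|
| starmap-like | 1,200 (square grid) | 1,000 | 7 layers | NB (r=2) | ≈ 80% |
| visium-like | 3,800 (hex grid) | 1,000 | 7 layers | NB (r=2) | ≈ 80% |
| slideseq-like | 5,000 (random) | 1,000 | 6 layers | ZINB (r=0.5, π=0.45) | ≈ 98% |

Library-size ranges and the gene-mean spread were calibrated so the
realized zero fractions match the platform sparsity regimes the presets
emulate. Gene counts are scaled down from the real platforms
(1,000 vs. 20,000+) so the full pipeline runs in minutes on one CPU;
spot counts are at or near platform scale for STARmap and scaled down
for the bead-based regime.

What the fixtures do *not* emulate: cell-type mixtures within spots,
spatially varying library size or capture efficiency, batch and section
effects, histology, or irregular domain shapes beyond
layers/rings/Voronoi patches. Passing recovery tests therefore
demonstrates the machinery works under the stated noise model, not
performance on real tissue.

## Determinism

Every stochastic component (weight init, dropout streams, EM starts,
fixture draws) derives from an explicit integer seed through
`numpy.random.default_rng`; two runs with equal seeds and configs
produce identical labels.

## Known limitations

* Full-batch training assumes the densified expression matrix fits in
  memory; there is no minibatch mode.
* The attention parametrization (softmax over sources of s_i + t_j)
  shares the source ranking across targets within a layer, as in the
  standard single-head formulation; it cannot express a per-target
  identity map, so the local objective is only achievable for features
  that vary smoothly over the graph.
* Single slide only: no multi-section integration, no histology, and no
  3-D coordinates.
* mclust-style model-based clustering is approximated by a Gaussian
  mixture with selectable covariance structure; the exact mclust model
  family and its hierarchical initialization are not reproduced.
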