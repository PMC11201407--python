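# sece

Spatial-domain identification for spatial transcriptomics.

Spatial transcriptomics assays (STARmap, Visium, Slide-seqV2,
Stereo-seq, ...) measure a spot × gene count matrix together with the
planar position of every spot. A central analysis step is segmenting
the tissue into *spatial domains* — contiguous regions with a coherent
expression program, such as cortical layers — which requires combining
expression similarity with spatial proximity. This package implements a
three-stage pipeline for that problem:

1. **Count-model autoencoder.** Library-size-normalized, log1p
   expression X̃ is compressed by a two-layer ReLU encoder into a
   32-dimensional expression embedding **Z**; the decoder parametrizes a
   negative-binomial (NB) or zero-inflated NB (ZINB) model of the raw
   counts, `ZINB(x; π, r, p) = π δ₀(x) + (1−π) NB(x; r, p)`, trained by
   mean negative log-likelihood (Adam, lr 1e-3, 40 iterations). ZINB
   suits highly sparse platforms; NB suits denser ones.
2. **Graph attention with a global spatial constraint.** Coordinates
   become a k-nearest-neighbor adjacency (k = 6 for Visium's hex
   lattice, 10 otherwise) and a Gaussian similarity matrix
   `Σ_ij = exp(−‖y_i − y_j‖²/(2γ))` with γ set to the 0.05 quantile of
   pairwise squared distances. Two attention layers transform Z into the
   spatial embedding **U** by minimizing
   `λ_global · MSE(UUᵀ, Σ) + λ_local · MSE(U, Z)` (Adam, lr 1e-2,
   50 iterations; λ_local = 1, λ_global = 0.08/0.3/2 by platform).
3. **Clustering and evaluation.** A seeded Gaussian-mixture EM clusters
   U into a user-chosen number of domains. Metrics: ARI, Kuhn–Munkres
   matched accuracy (ACC), average silhouette width (ASW) and the
   spatial local inverse Simpson index (LISI).

A synthetic-fixture generator produces layered/ring tissues with
domain-specific (ZI)NB programs at platform-like sparsity, so the whole
pipeline is testable without downloads. Model training runs on a small
in-repo numpy autodiff engine; no GPU or deep-learning framework is
required.

See `docs/methods.md` for the full model description, parameter
defaults and design rationale.

## Worked example

Simulate a 7-layer in-situ-style dataset, segment it, and score the
result:

```sh
sece simulate --preset starmap-like --out fixture/
sece run --counts fixture/counts.mtx --coords fixture/coords.csv \
         --n-domains 7 --platform starmap --out labels.csv \
         --embedding-out embedding.csv
sece eval --truth fixture/truth.csv --pred labels.csv \
          --coords fixture/coords.csv --embedding embedding.csv
```

The three commands print:

```
wrote starmap-like fixture (1200 spots x 1000 genes, 79.6% zeros) to fixture
wrote 7 domains for 1200 spots to labels.csv
{
  "ari": 0.9688755967884954,
  "acc": 0.9866666666666667,
  "asw": 0.5227390725856739,
  "lisi_normalized": 0.22293498540756493,
  "lisi": 1.5605448978529546
}
```

ARI/ACC near 1 mean the recovered domains agree with the generative
ground truth almost spot-for-spot; ASW ≈ 0.52 says the spatial
embedding separates the layers geometrically; mean LISI ≈ 1.56 labels
per 30-spot spatial neighborhood (0.22 after dividing by the 7 domains)
reflects tight spatial aggregation — boundary neighborhoods see two
layers, interior ones see one.

The same pipeline is available as a library:

```python
from sece import generate_preset, run_pipeline, ari

counts, coords, truth = generate_preset("starmap-like")
result = run_pipeline(counts, coords, n_domains=7, platform="starmap", seed=0)
print(ari(truth.labels, result.labeling.labels))
```

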