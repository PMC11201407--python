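"""End-to-end orchestration: counts + coordinates -> spatial domains.

Stages: filter -> normalize -> count-model AE (expression embedding Z)
-> spatial graph (adjacency + Gaussian similarity) -> GAT with the
local/global objective (spatial embedding U) -> Gaussian-mixture
clustering. Platform presets bundle the per-assay defaults:

=============  ===========  ==  =============  =======
platform       spot/gene     k  lambda_global  family
               filter
=============  ===========  ==  =============  =======
stereo-seq     200 / 20     10  0.08           zinb
slide-seqv2    20 / 20      10  0.08           zinb
visium         20 / 20       6  0.3            nb
starmap        20 / 20      10  2.0            nb
=============  ===========  ==  =============  =======
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ae import AEConfig, ExpressionFeatures, train_ae
from .cluster import ClusteringConfig, cluster_embedding
from .gat import GATConfig, LAMBDA_GLOBAL_PRESETS, SpatialEmbedding, train_gat
from .graph import K_PRESETS, SpatialGraph, build_graph
from .io import CountMatrix, CoordinateTable, DomainLabeling
from .preprocess import FILTER_PRESETS, filter_spots_genes, normalize_log

FAMILY_PRESETS: dict[str, str] = {
    "stereo-seq": "zinb",
    "slide-seqv2": "zinb",
    "visium": "nb",
    "starmap": "nb",
}

PLATFORMS = tuple(FAMILY_PRESETS)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; ``for_platform`` fills in the presets."""

    min_spot_counts: int = 20
    min_gene_spots: int = 20
    target_sum: float | str = "auto"
    k: int = 10
    gamma: float | str = "auto"
    kernel_halving: bool = True
    gamma_on: str = "squared"
    ae: AEConfig = field(default_factory=AEConfig)
    gat: GATConfig = field(default_factory=GATConfig)
    covariance_model: str = "shared-full"
    n_init: int = 10
    seed: int = 0

    @classmethod
    def for_platform(cls, platform: str, seed: int = 0) -> "PipelineConfig":
        if platform not in PLATFORMS:
            raise ValueError(f"unknown platform {platform!r}; choose from {PLATFORMS}")
        min_spot, min_gene = FILTER_PRESETS[platform]
        return cls(
            min_spot_counts=min_spot,
            min_gene_spots=min_gene,
            k=K_PRESETS[platform],
            ae=AEConfig(family=FAMILY_PRESETS[platform], seed=seed),
            gat=GATConfig(lambda_global=LAMBDA_GLOBAL_PRESETS[platform], seed=seed),
            seed=seed,
        )

    def reseeded(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed,
                       ae=replace(self.ae, seed=seed),
                       gat=replace(self.gat, seed=seed))


@dataclass
class PipelineResult:
    labeling: DomainLabeling
    embedding: SpatialEmbedding
    features: ExpressionFeatures
    graph: SpatialGraph
    counts: CountMatrix
    coords: CoordinateTable


def run_pipeline(counts: CountMatrix, coords: CoordinateTable, n_domains: int,
                 config: PipelineConfig | None = None,
                 platform: str | None = None, seed: int | None = None) -> PipelineResult:
    """Run the full method and return labels plus all intermediate products."""
    if config is None:
        config = (PipelineConfig.for_platform(platform, seed=seed or 0)
                  if platform else PipelineConfig())
    if seed is not None:
        config = config.reseeded(seed)

    filtered = filter_spots_genes(counts, config.min_spot_counts, config.min_gene_spots)
    keep = {s: i for i, s in enumerate(coords.spot_ids)}
    order = np.array([keep[s] for s in filtered.spot_ids])
    coords_f = CoordinateTable(coords.coords[order], filtered.spot_ids)

    xnorm = normalize_log(filtered, config.target_sum)
    features, _ = train_ae(xnorm, filtered, config.ae)

    graph = build_graph(coords_f, k=config.k, gamma=config.gamma,
                        kernel_halving=config.kernel_halving,
                        gamma_on=config.gamma_on, seed=config.seed)
    embedding = train_gat(features.z, graph, config.gat)

    labeling = cluster_embedding(embedding.u, ClusteringConfig(
        n_domains=n_domains, covariance_model=config.covariance_model,
        n_init=config.n_init, seed=config.seed))
    return PipelineResult(labeling=labeling, embedding=embedding, features=features,
                          graph=graph, counts=filtered, coords=coords_f)
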