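"""Spot/gene filtering and library-size normalization.

Filtering removes low-coverage spots first (total counts below a
threshold), then genes detected in too few of the remaining spots.
Normalization scales each spot to a common target sum and applies
``log1p``, so zeros stay exactly zero. Platform presets follow the
conventions used on each assay: high-resolution Stereo-seq data uses a
200-count spot threshold, other platforms 20; the gene threshold is 20
spots everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix, ValidationError

#: (min_spot_counts, min_gene_spots) per platform
FILTER_PRESETS: dict[str, tuple[int, int]] = {
    "stereo-seq": (200, 20),
    "slide-seqv2": (20, 20),
    "visium": (20, 20),
    "starmap": (20, 20),
}


@dataclass
class NormalizedExpression:
    """Log library-size-normalized expression plus the per-spot library sizes."""

    xnorm: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.xnorm = np.asarray(self.xnorm, dtype=np.float64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.float64)
        if not np.all(np.isfinite(self.xnorm)) or self.xnorm.min(initial=0) < 0:
            raise ValidationError("normalized expression must be finite and nonnegative")
        if np.any(self.library_sizes <= 0):
            raise ValidationError("library sizes must be positive")


def filter_spots_genes(m: CountMatrix, min_spot_counts: int = 20,
                       min_gene_spots: int = 20) -> CountMatrix:
    """Drop low-coverage spots, then genes detected in too few remaining spots.

    Gene prevalence (number of spots with count > 0) is recomputed on the
    spot-filtered matrix, so the two passes are ordered and deterministic.
    Survivor order is preserved.
    """
    if min_spot_counts < 0 or min_gene_spots < 0:
        raise ValueError("thresholds must be nonnegative")
    spot_keep = m.counts.sum(axis=1) >= min_spot_counts
    if not spot_keep.any():
        raise ValidationError(
            f"all {m.n_spots} spots fall below min_spot_counts={min_spot_counts}; lower the threshold")
    sub = m.counts[spot_keep]
    gene_keep = (sub > 0).sum(axis=0) >= min_gene_spots
    if not gene_keep.any():
        raise ValidationError(
            f"all {m.n_genes} genes are below min_gene_spots={min_gene_spots}; lower the threshold")
    return CountMatrix(sub[:, gene_keep], m.spot_ids[spot_keep], m.gene_ids[gene_keep])


def normalize_log(m: CountMatrix, target_sum: float | str = "auto") -> NormalizedExpression:
    """log1p of counts rescaled so each spot sums to ``target_sum``.

    ``xnorm[n, g] = log(1 + counts[n, g] * target_sum / library_size[n])``.
    ``target_sum="auto"`` uses the median library size, which makes the
    transform scale-free across platforms.
    """
    lib = m.counts.sum(axis=1).astype(np.float64)
    if np.any(lib == 0):
        bad = m.spot_ids[np.argmax(lib == 0)]
        raise ValidationError(f"spot {bad!r} has zero library size; filter spots first")
    if target_sum == "auto":
        target = float(np.median(lib))
    else:
        target = float(target_sum)
        if target <= 0:
            raise ValueError("target_sum must be positive")
    xnorm = np.log1p(m.counts * (target / lib)[:, None])
    return NormalizedExpression(xnorm, lib)
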