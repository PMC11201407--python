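"""Local spatial adjacency and global Gaussian spatial similarity.

Two complementary views of the coordinates feed the embedding model:

* the adjacency matrix ``A`` (binary, symmetric) marks each spot's
  k nearest spatial neighbors (OR-symmetrized, self excluded) and drives
  the graph-attention aggregation;
* the similarity matrix ``Sigma`` with entries
  ``exp(-||y_i - y_j||^2 / (2 gamma))`` encodes global proximity and is
  the target of the embedding's Gram-matrix constraint. The bandwidth
  ``gamma`` defaults to the 0.05 quantile of pairwise *squared*
  distances, which makes ``Sigma`` invariant to uniform rescaling of the
  coordinates (platform units never matter).

Default neighbor counts follow platform geometry: 6 on the hexagonal
Visium lattice, 10 elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .io import CoordinateTable

logger = logging.getLogger(__name__)

#: KNN neighbor count per platform
K_PRESETS: dict[str, int] = {
    "visium": 6,
    "stereo-seq": 10,
    "slide-seqv2": 10,
    "starmap": 10,
}

#: quantile of pairwise squared distances defining the auto bandwidth
GAMMA_QUANTILE = 0.05

#: above this N the bandwidth quantile is estimated from a subsample
_QUANTILE_SUBSAMPLE_AT = 20_000
_QUANTILE_SUBSAMPLE_SIZE = 10_000


@dataclass
class SpatialGraph:
    """Binary adjacency plus dense Gaussian similarity for one slide."""

    adjacency: np.ndarray
    sim: np.ndarray
    k: int
    gamma: float


def build_adjacency(coords: CoordinateTable, k: int = 10, mode: str = "knn",
                    radius: float | None = None) -> np.ndarray:
    """Binary symmetric spatial adjacency with zero diagonal.

    ``knn`` connects i and j when either is among the other's k nearest
    (OR symmetrization), so every row has at least k ones. Exact-distance
    ties are broken by spot index order. ``radius`` mode connects all
    pairs with 0 < d <= radius.
    """
    y = coords.coords
    n = len(y)
    if mode == "radius":
        if radius is None or radius <= 0:
            raise ValueError("radius mode requires radius > 0")
        d = squareform(pdist(y))
        a = (d > 0) & (d <= radius)
        np.fill_diagonal(a, False)
        return a.astype(np.int8)
    if mode != "knn":
        raise ValueError(f"unknown adjacency mode {mode!r}")
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < N, got k={k}, N={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(y)
    _, idx = nn.kneighbors(y)
    a = np.zeros((n, n), dtype=np.int8)
    rows = np.repeat(np.arange(n), k)
    # drop each spot's own entry; duplicate coordinates may push it out of
    # column 0, so mask explicitly (index-order tie-break comes from sklearn)
    cols = []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        if len(neigh) < k:  # duplicates collapsed; pad from remaining order
            logger.warning("duplicate coordinates near spot %d; tie-break by index", i)
            extra = [j for j in range(n) if j != i and j not in neigh]
            neigh = neigh + extra[: k - len(neigh)]
        cols.extend(neigh)
    a[rows, np.asarray(cols)] = 1
    a = np.maximum(a, a.T)  # OR symmetrization
    np.fill_diagonal(a, 0)
    return a


def _auto_gamma(y: np.ndarray, gamma_on: str, seed: int = 0) -> float:
    n = len(y)
    if n > _QUANTILE_SUBSAMPLE_AT:
        rng = np.random.default_rng(seed)
        y = y[rng.choice(n, _QUANTILE_SUBSAMPLE_SIZE, replace=False)]
        logger.info("estimating gamma quantile from a %d-spot subsample", len(y))
    d2 = pdist(y, metric="sqeuclidean")
    if gamma_on == "unsquared":
        gamma = float(np.quantile(np.sqrt(d2), GAMMA_QUANTILE))
    else:
        gamma = float(np.quantile(d2, GAMMA_QUANTILE))
    return gamma


def build_ssm(coords: CoordinateTable, gamma: float | str = "auto",
              kernel_halving: bool = True, gamma_on: str = "squared",
              seed: int = 0) -> tuple[np.ndarray, float]:
    """Dense Gaussian spatial similarity and the bandwidth actually used.

    ``Sigma_ij = exp(-d_ij^2 / (2 gamma))`` (``kernel_halving=False``
    drops the factor 2). ``gamma="auto"`` takes the 0.05 quantile of
    pairwise squared distances (``gamma_on="unsquared"`` switches to the
    quantile of plain distances, for sensitivity checks).
    """
    y = coords.coords
    if gamma == "auto":
        g = _auto_gamma(y, gamma_on, seed)
        if g <= 0:
            raise ValueError("auto bandwidth is zero (coincident coordinates); pass gamma explicitly")
    else:
        g = float(gamma)
        if g <= 0:
            raise ValueError("gamma must be positive")
    d2 = squareform(pdist(y, metric="sqeuclidean"))
    denom = 2.0 * g if kernel_halving else g
    sim = np.exp(-d2 / denom)
    np.fill_diagonal(sim, 1.0)
    return sim, g


def ssm_rows(coords: CoordinateTable, rows: np.ndarray, gamma: float,
             kernel_halving: bool = True) -> np.ndarray:
    """A row block of the similarity matrix, for blockwise loss evaluation."""
    y = coords.coords
    diff = y[rows, None, :] - y[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    denom = 2.0 * gamma if kernel_halving else gamma
    out = np.exp(-d2 / denom)
    out[np.arange(len(rows)), rows] = 1.0
    return out


def build_graph(coords: CoordinateTable, k: int = 10, gamma: float | str = "auto",
                mode: str = "knn", radius: float | None = None,
                kernel_halving: bool = True, gamma_on: str = "squared",
                seed: int = 0) -> SpatialGraph:
    """Convenience constructor bundling adjacency and similarity."""
    a = build_adjacency(coords, k=k, mode=mode, radius=radius)
    sim, g = build_ssm(coords, gamma=gamma, kernel_halving=kernel_halving,
                       gamma_on=gamma_on, seed=seed)
    if not _is_connected(a):
        logger.warning("spatial adjacency graph is not connected")
    return SpatialGraph(adjacency=a, sim=sim, k=k if mode == "knn" else 0, gamma=g)


def _is_connected(a: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components
    from scipy import sparse
    ncomp, _ = connected_components(sparse.csr_matrix(a), directed=False)
    return ncomp == 1
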