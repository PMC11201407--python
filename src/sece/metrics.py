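"""Evaluation metrics: ARI, Hungarian-matched accuracy, ASW and spatial LISI.

ARI is computed from the contingency table with pair counts C(n, 2);
matched accuracy maps predicted to true labels by solving the optimal
assignment on the contingency table (Kuhn–Munkres); ASW is the mean
silhouette width of the embedding under the given labels; LISI is the
local inverse Simpson index of labels within each spot's spatial
neighborhood (smaller = stronger spatial aggregation).

Note on LISI: the inverse *Simpson* index 1 / sum_l p(l)^2 is used (the
naive reciprocal of summed probabilities is identically one). The
unnormalized index lives in [1, |L|]; ``normalized=True`` divides by the
number of domains to map it into (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .io import CoordinateTable, DomainLabeling

#: default spatial neighborhood size for LISI
LISI_NEIGHBORS = 30


def _labels(x) -> np.ndarray:
    if isinstance(x, DomainLabeling):
        return np.asarray(x.labels)
    return np.asarray(x)


@dataclass
class ContingencyTable:
    """Cross-tabulation of two labelings with its margins."""

    n_ij: np.ndarray
    a_i: np.ndarray
    b_j: np.ndarray
    N: int

    @classmethod
    def from_labels(cls, truth, pred) -> "ContingencyTable":
        t, p = _labels(truth), _labels(pred)
        if len(t) != len(p):
            raise ValueError(f"label length mismatch: {len(t)} vs {len(p)}")
        t_codes, t_idx = np.unique(t, return_inverse=True)
        p_codes, p_idx = np.unique(p, return_inverse=True)
        n_ij = np.zeros((len(t_codes), len(p_codes)), dtype=np.int64)
        np.add.at(n_ij, (t_idx, p_idx), 1)
        return cls(n_ij, n_ij.sum(axis=1), n_ij.sum(axis=0), len(t))


def ari(truth, pred) -> float:
    """Adjusted Rand index in [-1, 1] from the contingency table."""
    ct = ContingencyTable.from_labels(truth, pred)
    sum_ij = comb(ct.n_ij, 2).sum()
    sum_a = comb(ct.a_i, 2).sum()
    sum_b = comb(ct.b_j, 2).sum()
    pairs = comb(ct.N, 2)
    expected = sum_a * sum_b / pairs
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def acc(truth, pred) -> float:
    """Accuracy after the optimal one-to-one relabeling of predictions.

    The assignment maximizing total matches is found on the contingency
    table; a rectangular table is zero-padded to square so unmatched
    predicted labels simply count as errors.
    """
    ct = ContingencyTable.from_labels(truth, pred)
    size = max(ct.n_ij.shape)
    cost = np.zeros((size, size), dtype=np.int64)
    cost[: ct.n_ij.shape[0], : ct.n_ij.shape[1]] = ct.n_ij
    rows, cols = linear_sum_assignment(cost, maximize=True)
    return float(cost[rows, cols].sum() / ct.N)


def asw(embedding: np.ndarray, labels) -> float:
    """Mean silhouette width of the embedding under the labels.

    Euclidean distance; spots in singleton clusters contribute 0.
    """
    lab = _labels(labels)
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim != 2 or len(emb) != len(lab):
        raise ValueError("embedding must be N x m and match the labels")
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(np.mean(silhouette_samples(emb, lab)))


def lisi(coords: CoordinateTable | np.ndarray, labels,
         neighborhood_size: int = LISI_NEIGHBORS,
         normalized: bool = True) -> tuple[np.ndarray, float]:
    """Per-spot local inverse Simpson index of labels, plus its mean.

    For each spot, ``p(l)`` is the fraction of its ``neighborhood_size``
    spatial nearest neighbors (self included) with label ``l``;
    ``LISI_i = 1 / sum_l p(l)^2``, optionally divided by the number of
    domains so that 1 means maximal local mixing.
    """
    y = coords.coords if isinstance(coords, CoordinateTable) else np.asarray(coords)
    lab = _labels(labels)
    n = len(y)
    if neighborhood_size >= n:
        raise ValueError(f"neighborhood_size must be < N={n}")
    if len(lab) != n:
        raise ValueError("labels must match coordinates")
    codes, idx = np.unique(lab, return_inverse=True)
    n_lab = len(codes)
    nn = NearestNeighbors(n_neighbors=neighborhood_size).fit(y)
    _, neigh = nn.kneighbors(y)
    counts = np.zeros((n, n_lab))
    np.add.at(counts, (np.repeat(np.arange(n), neighborhood_size), idx[neigh].ravel()), 1)
    p = counts / neighborhood_size
    values = 1.0 / np.sum(p ** 2, axis=1)
    if normalized:
        values = values / n_lab
    return values, float(values.mean())
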