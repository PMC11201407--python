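"""Spatial embedding via graph attention with a global similarity constraint.

Two graph-attention layers aggregate each spot's neighborhood (self
included) with softmax-normalized attention scores
``e_ij = a^T [W h_i || W h_j]``, starting from the expression embedding
Z. Training balances two objectives:

* local: ``MSE(U, Z)`` — the embedding should preserve expression
  features;
* global: ``MSE(U U^T, Sigma)`` — the Gram matrix of the embedding
  should match the Gaussian spatial similarity of the coordinates.

``loss = lambda_global * L_global + lambda_local * L_local`` with
``lambda_local = 1``; ``lambda_global`` is platform dependent (0.08 for
Stereo-seq/Slide-seqV2, 0.3 for Visium, 2 for STARmap). ELU is applied
inside the first layer; the final layer is linear by default so the
Gram-matrix fit is unconstrained in sign.

The global loss supports blockwise evaluation against lazily computed
similarity rows, so the dense N×N matrix never needs to be materialized
for large slides; blockwise and dense evaluation are mathematically
identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from ._optim import Adam
from .graph import SpatialGraph

#: platform presets for the global-loss weight
LAMBDA_GLOBAL_PRESETS: dict[str, float] = {
    "stereo-seq": 0.08,
    "slide-seqv2": 0.08,
    "visium": 0.3,
    "starmap": 2.0,
}

#: row-block size for blockwise global-loss evaluation
_BLOCK = 2048


@dataclass
class GATConfig:
    layer_dims: tuple[int, int] = (32, 32)
    learning_rate: float = 1e-2
    dropout: float = 0.2
    iterations: int = 50
    lambda_global: float = 0.3
    lambda_local: float = 1.0
    final_activation: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_global < 0 or self.lambda_local < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_global == 0 and self.lambda_local == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.final_activation not in ("identity", "elu"):
            raise ValueError(f"unknown final_activation {self.final_activation!r}")


@dataclass
class SpatialEmbedding:
    """GAT output U with the per-iteration loss trace."""

    u: np.ndarray
    training_history: list[dict] = field(default_factory=list)
    #: norm by which the expression embedding was divided before training
    z_scale: float = 1.0


class _EdgeGraph:
    """Edge-list view of the aggregation sets, sorted by target node.

    Attention is evaluated only on the graph's edges (plus self-loops):
    the spatial adjacency is sparse (k neighbors out of N), so edge-list
    softmax and scipy-sparse aggregation replace the dense N×N path.
    """

    __slots__ = ("n", "src", "dst", "indptr")

    def __init__(self, adjacency: np.ndarray):
        a = (np.asarray(adjacency) > 0) | np.eye(len(adjacency), dtype=bool)
        self.n = len(a)
        # iterate a.T row-major so edges come out sorted by target
        dst, src = np.nonzero(a.T)
        self.src = src
        self.dst = dst
        self.indptr = np.searchsorted(dst, np.arange(self.n + 1))
        if np.any(np.diff(self.indptr) < 1):
            raise ValueError("every node needs at least one aggregation neighbor")

    @property
    def n_edges(self) -> int:
        return len(self.src)


def _attention_aggregate(wh: Tensor, s: Tensor, t: Tensor, eg: _EdgeGraph,
                         drop_mask: np.ndarray | None) -> tuple[Tensor, np.ndarray]:
    """Fused edge softmax + neighborhood aggregation.

    ``e_ij = s_i + t_j`` on edges (i -> j); alpha is the per-target
    softmax; output row j is ``sum_i alpha_ij (Wh)_i``. Returns the
    aggregated features and the per-target attention sums (pre-dropout),
    which are identically one up to rounding.
    """
    from scipy import sparse

    src, dst, indptr = eg.src, eg.dst, eg.indptr
    e = s.data[src] + t.data[dst]
    seg_max = np.maximum.reduceat(e, indptr[:-1])
    w = np.exp(e - seg_max[dst])
    denom = np.add.reduceat(w, indptr[:-1])
    alpha = w / denom[dst]
    att_sums = np.add.reduceat(alpha, indptr[:-1])
    used = alpha if drop_mask is None else alpha * drop_mask
    mat = sparse.csr_matrix((used, src, indptr), shape=(eg.n, eg.n))
    out = mat @ wh.data

    def backward(g):
        dwh = mat.T @ g
        dused = np.einsum("em,em->e", g[dst], wh.data[src])
        dalpha = dused if drop_mask is None else dused * drop_mask
        inner = np.add.reduceat(alpha * dalpha, indptr[:-1])
        de = alpha * (dalpha - inner[dst])
        ds = np.bincount(src, weights=de, minlength=eg.n)
        dt = np.bincount(dst, weights=de, minlength=eg.n)
        return dwh, ds, dt

    return Tensor._node(out, (wh, s, t), backward), att_sums


def _layer_forward(h: Tensor, w: Tensor, a_vec: Tensor, eg: _EdgeGraph,
                   activation: str, drop_mask: np.ndarray | None = None
                   ) -> tuple[Tensor, np.ndarray]:
    """One attention layer; returns (features, attention sums per node)."""
    out_dim = w.shape[0]
    wh = h @ w.T                                  # N x out
    a_l = Tensor._node(a_vec.data[:out_dim], (a_vec,),
                       lambda g: (np.concatenate([g, np.zeros(out_dim)]),))
    a_r = Tensor._node(a_vec.data[out_dim:], (a_vec,),
                       lambda g: (np.concatenate([np.zeros(out_dim), g]),))
    s = wh @ a_l                                   # source score, length N
    t = wh @ a_r                                   # target score, length N
    h_new, att_sums = _attention_aggregate(wh, s, t, eg, drop_mask)
    if activation == "elu":
        h_new = ag.elu(h_new)
    return h_new, att_sums


def gat_layer_forward(h: np.ndarray, adjacency: np.ndarray, w: np.ndarray,
                      a: np.ndarray, activation: str = "elu") -> np.ndarray:
    """Single attention layer on concrete arrays (no dropout, no gradients).

    ``w`` is (out_dim, in_dim); ``a`` is the length-2*out_dim attention
    vector. Every node's aggregation set is its adjacency neighborhood
    plus itself.
    """
    out, _ = _layer_forward(Tensor(h), Tensor(w), Tensor(a),
                            _EdgeGraph(adjacency), activation)
    return out.data


SimSource = np.ndarray | Callable[[np.ndarray], np.ndarray]


def _sim_block(sim: SimSource, start: int, stop: int) -> np.ndarray:
    if isinstance(sim, np.ndarray):
        return sim[start:stop]  # view, no copy
    return sim(np.arange(start, stop))


def _global_mse(u: Tensor, sim: SimSource, n: int) -> Tensor:
    """Blockwise MSE(U U^T, Sigma) over all N^2 entries, diagonal included.

    The gradient uses d/dU = (4/N^2)(U U^T - Sigma) U, which requires
    Sigma to be symmetric (always true for a distance kernel).
    """
    total = 0.0
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        d = u.data[start:stop] @ u.data.T - _sim_block(sim, start, stop)
        total += float(np.sum(d * d))
    total /= n * n

    def backward(g):
        grad = np.empty_like(u.data)
        for start in range(0, n, _BLOCK):
            stop = min(start + _BLOCK, n)
            d = u.data[start:stop] @ u.data.T - _sim_block(sim, start, stop)
            grad[start:stop] = d @ u.data
        return (g * (4.0 / (n * n)) * grad,)

    return Tensor._node(np.asarray(total), (u,), backward)


def compute_losses(u: np.ndarray, z: np.ndarray, sim: SimSource,
                   cfg: GATConfig) -> tuple[float, float, float]:
    """(total, local, global) losses for concrete arrays.

    local = mean((U - Z)^2); global = mean((U U^T - Sigma)^2) over all
    N^2 entries; total = lambda_global * global + lambda_local * local.
    """
    u = np.asarray(u, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if u.shape != z.shape:
        raise ValueError(f"U {u.shape} and Z {z.shape} shapes differ")
    local = float(np.mean((u - z) ** 2))
    n = len(u)
    glob = _global_mse(Tensor(u), sim, n).item()
    total = cfg.lambda_global * glob + cfg.lambda_local * local
    return total, local, glob


class GraphAttention:
    """Two-layer attention model with seeded initialization."""

    def __init__(self, in_dim: int, cfg: GATConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d1, d2 = cfg.layer_dims

        def glorot(fan_out, fan_in):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_out, fan_in))

        # attention vectors start at zero: the first forward pass is plain
        # neighborhood averaging, a well-conditioned starting point
        self.params = {
            "w1": Tensor(glorot(d1, in_dim), requires_grad=True),
            "a1": Tensor(np.zeros(2 * d1), requires_grad=True),
            "w2": Tensor(glorot(d2, d1), requires_grad=True),
            "a2": Tensor(np.zeros(2 * d2), requires_grad=True),
        }

    def calibrate_output_scale(self, z: np.ndarray, eg: _EdgeGraph) -> None:
        """Rescale the output layer so initial embeddings have unit row norm.

        The Gram-matrix target has entries in (0, 1], so starting U at unit
        scale lets the short training schedule spend its steps on geometry
        rather than on walking the overall scale down.
        """
        u0, _ = self.forward(z, eg, rng=None)
        norm = float(np.mean(np.linalg.norm(u0.data, axis=1)))
        if norm > 0:
            self.params["w2"].data /= norm

    def forward(self, z: np.ndarray, eg: _EdgeGraph,
                rng: np.random.Generator | None = None) -> tuple[Tensor, list[np.ndarray]]:
        cfg = self.cfg
        h: Tensor = Tensor(z)
        drop = cfg.dropout if rng is not None else 0.0
        att_masks = [None, None]
        if drop:
            h = h * ((rng.random(h.shape) >= drop) / (1.0 - drop))
            att_masks = [(rng.random(eg.n_edges) >= drop) / (1.0 - drop)
                         for _ in range(2)]
        h1, sums1 = _layer_forward(h, self.params["w1"], self.params["a1"],
                                   eg, "elu", att_masks[0])
        h2, sums2 = _layer_forward(h1, self.params["w2"], self.params["a2"],
                                   eg, cfg.final_activation, att_masks[1])
        return h2, [sums1, sums2]


def train_gat(z: np.ndarray, graph: SpatialGraph | None, cfg: GATConfig,
              adjacency: np.ndarray | None = None,
              sim: SimSource | None = None) -> SpatialEmbedding:
    """Full-batch Adam on the combined local/global objective.

    Accepts either a :class:`SpatialGraph` or explicit adjacency and
    similarity (the latter possibly a callable returning row blocks).
    The expression embedding is divided by its mean row norm first (the
    factor is reported as ``z_scale``), so the losses in
    ``training_history`` refer to the unit-scale target. Returns U from a
    final evaluation-mode pass; deterministic given the seed.
    """
    if graph is not None:
        adjacency, sim = graph.adjacency, graph.sim
    if adjacency is None or sim is None:
        raise ValueError("need a SpatialGraph or explicit adjacency and sim")
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("expression embedding contains non-finite values")
    # rescale the expression embedding to unit mean row norm: the local
    # reconstruction target then lives on the same scale as the Gram-matrix
    # similarity target, so the two objectives are not fighting over scale
    z_scale = float(np.mean(np.linalg.norm(z, axis=1)))
    if z_scale > 0:
        z = z / z_scale
    n = len(z)
    eg = _EdgeGraph(adjacency)
    model = GraphAttention(z.shape[1], cfg)
    model.calibrate_output_scale(z, eg)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(list(model.params.values()), lr=cfg.learning_rate)
    history: list[dict] = []
    for it in range(cfg.iterations):
        opt.zero_grad()
        u, att_sums = model.forward(z, eg, rng)
        local = ag.square(u - z).mean()
        glob = _global_mse(u, sim, n)
        loss = cfg.lambda_global * glob + cfg.lambda_local * local
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite GAT loss at iteration {it}")
        loss.backward()
        opt.step()
        history.append({
            "loss": value,
            "loss_local": local.item(),
            "loss_global": glob.item(),
            "attention_sum_dev": float(max(np.abs(s - 1.0).max() for s in att_sums)),
        })
    u_final, _ = model.forward(z, eg, rng=None)  # eval mode
    return SpatialEmbedding(u=u_final.data, training_history=history, z_scale=z_scale)
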