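"""Graph-attention forward/loss oracles and training behavior."""

import numpy as np
import pytest

import sece._autograd as ag
from sece._autograd import Tensor
from sece.gat import (GATConfig, LAMBDA_GLOBAL_PRESETS, _EdgeGraph, _global_mse,
                      _layer_forward, compute_losses, gat_layer_forward, train_gat)
from sece.graph import SpatialGraph, build_graph
from sece.io import CoordinateTable


def _hand_gat_layer(h, adjacency, w, a, elu=True):
    """Scalar-loop reference: e_ij = a^T [Wh_i || Wh_j], softmax over i in N_j."""
    n, _ = h.shape
    out_dim = w.shape[0]
    wh = np.array([w @ h[i] for i in range(n)])
    out = np.zeros((n, out_dim))
    for j in range(n):
        neigh = [i for i in range(n) if adjacency[i, j] or i == j]
        e = np.array([a @ np.concatenate([wh[i], wh[j]]) for i in neigh])
        alpha = np.exp(e - e.max())
        alpha /= alpha.sum()
        agg = sum(al * wh[i] for al, i in zip(alpha, neigh))
        out[j] = np.where(agg > 0, agg, np.expm1(np.minimum(agg, 0))) if elu else agg
    return out


@pytest.fixture
def toy_graph():
    adj = np.array([
        [0, 1, 1, 0, 0, 0],
        [1, 0, 1, 0, 0, 0],
        [1, 1, 0, 1, 0, 0],
        [0, 0, 1, 0, 1, 1],
        [0, 0, 0, 1, 0, 1],
        [0, 0, 0, 1, 1, 0],
    ])
    return adj


def test_layer_matches_scalar_loop_oracle(toy_graph, rng):
    h = rng.normal(size=(6, 4))
    w = rng.normal(size=(3, 4)) * 0.5
    a = rng.normal(size=6) * 0.5
    ours = gat_layer_forward(h, toy_graph, w, a, activation="elu")
    ref = _hand_gat_layer(h, toy_graph, w, a, elu=True)
    assert np.allclose(ours, ref, atol=1e-6)
    ours_lin = gat_layer_forward(h, toy_graph, w, a, activation="identity")
    ref_lin = _hand_gat_layer(h, toy_graph, w, a, elu=False)
    assert np.allclose(ours_lin, ref_lin, atol=1e-6)


def test_singleton_aggregation_set(rng):
    # isolated node with a self-loop: alpha = 1, output = ELU(Wh)
    adj = np.zeros((3, 3), dtype=int)
    adj[0, 1] = adj[1, 0] = 1
    h = rng.normal(size=(3, 2))
    w = rng.normal(size=(2, 2))
    a = rng.normal(size=4)
    out = gat_layer_forward(h, adj, w, a)
    wh2 = w @ h[2]
    assert np.allclose(out[2], np.where(wh2 > 0, wh2, np.expm1(wh2)), atol=1e-12)


def test_attention_sums_to_one(toy_graph, rng):
    h = Tensor(rng.normal(size=(6, 4)))
    w = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    a = Tensor(rng.normal(size=6), requires_grad=True)
    _, sums = _layer_forward(h, w, a, _EdgeGraph(toy_graph), "elu")
    assert np.allclose(sums, 1.0, atol=1e-12)


def test_attention_gradients_match_finite_differences(toy_graph, rng):
    h = rng.normal(size=(6, 4))
    w0 = rng.normal(size=(3, 4)) * 0.5
    a0 = rng.normal(size=6) * 0.5
    w = Tensor(w0.copy(), requires_grad=True)
    a = Tensor(a0.copy(), requires_grad=True)
    out, _ = _layer_forward(Tensor(h), w, a, _EdgeGraph(toy_graph), "elu")
    proj = rng.normal(size=out.shape)
    (out * proj).sum().backward()

    def f(wv, av):
        return (_hand_gat_layer(h, toy_graph, wv, av) * proj).sum()

    eps = 1e-6
    for t, v0, which in [(w, w0, "w"), (a, a0, "a")]:
        num = np.zeros_like(v0)
        it = np.nditer(v0, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            vp, vm = v0.copy(), v0.copy()
            vp[i] += eps
            vm[i] -= eps
            num[i] = ((f(vp, a0) - f(vm, a0)) if which == "w"
                      else (f(w0, vp) - f(w0, vm))) / (2 * eps)
        assert np.allclose(t.grad, num, atol=1e-5), which


class TestLosses:
    def test_zero_when_targets_met(self):
        n, m = 8, 3
        rng = np.random.default_rng(1)
        u = rng.normal(size=(n, m))
        sim = u @ u.T
        total, local, glob = compute_losses(u, u, sim, GATConfig(lambda_global=1.0))
        assert total == local == glob == 0.0

    def test_lambda_global_zero_degenerates(self, rng):
        u = rng.normal(size=(10, 3))
        z = rng.normal(size=(10, 3))
        sim = rng.random((10, 10))
        cfg = GATConfig(lambda_global=0.0, lambda_local=1.0)
        total, local, _ = compute_losses(u, z, sim, cfg)
        assert np.isclose(total, np.mean((u - z) ** 2), atol=1e-15)
        assert total == 1.0 * local

    def test_matches_double_loop_oracle(self, rng):
        u = rng.normal(size=(10, 3))
        z = rng.normal(size=(10, 3))
        sim = rng.random((10, 10))
        cfg = GATConfig(lambda_global=0.7, lambda_local=1.3)
        total, local, glob = compute_losses(u, z, sim, cfg)
        l_ref = sum((u[i, j] - z[i, j]) ** 2 for i in range(10) for j in range(3)) / 30
        gram = u @ u.T
        g_ref = sum((gram[i, j] - sim[i, j]) ** 2 for i in range(10) for j in range(10)) / 100
        assert np.isclose(local, l_ref, atol=1e-12)
        assert np.isclose(glob, g_ref, atol=1e-12)
        assert np.isclose(total, 0.7 * g_ref + 1.3 * l_ref, atol=1e-12)

    def test_blockwise_equals_dense(self, rng):
        u = rng.normal(size=(200, 5))
        coords_like = rng.random((200, 200))
        sim_dense = (coords_like + coords_like.T) / 2
        dense = _global_mse(Tensor(u), sim_dense, 200).item()

        def lazy_rows(rows):
            return sim_dense[rows]

        lazy = _global_mse(Tensor(u), lazy_rows, 200).item()
        assert np.isclose(dense, lazy, atol=1e-10)

    def test_global_mse_gradient(self, rng):
        u0 = rng.normal(size=(6, 2))
        sim = rng.random((6, 6))
        sim = (sim + sim.T) / 2  # the gradient formula assumes a symmetric kernel
        u = Tensor(u0.copy(), requires_grad=True)
        _global_mse(u, sim, 6).backward()
        eps = 1e-6
        num = np.zeros_like(u0)
        it = np.nditer(u0, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            up, um = u0.copy(), u0.copy()
            up[i] += eps
            um[i] -= eps
            num[i] = (np.mean((up @ up.T - sim) ** 2)
                      - np.mean((um @ um.T - sim) ** 2)) / (2 * eps)
        assert np.allclose(u.grad, num, atol=1e-6)


class TestTraining:
    def _graph(self, rng, n=60):
        coords = CoordinateTable(rng.random((n, 2)), [f"s{i}" for i in range(n)])
        return build_graph(coords, k=5)

    def test_loss_decreases(self, rng):
        g = self._graph(rng)
        z = rng.normal(size=(60, 8))
        cfg = GATConfig(layer_dims=(8, 8), lambda_global=0.3, seed=0)
        emb = train_gat(z, g, cfg)
        hist = emb.training_history
        assert hist[-1]["loss"] < hist[0]["loss"]
        assert all(np.isfinite(h["loss"]) for h in hist)

    def test_attention_normalized_every_step(self, rng):
        g = self._graph(rng)
        z = rng.normal(size=(60, 8))
        emb = train_gat(z, g, GATConfig(layer_dims=(8, 8), lambda_global=0.3, seed=0))
        assert max(h["attention_sum_dev"] for h in emb.training_history) < 1e-10

    def test_seeded_reproducibility(self, rng):
        g = self._graph(rng)
        z = rng.normal(size=(60, 8))
        cfg = GATConfig(layer_dims=(8, 8), lambda_global=0.3, seed=3)
        u1 = train_gat(z, g, cfg).u
        u2 = train_gat(z, g, cfg).u
        assert np.array_equal(u1, u2)

    def test_local_objective_achievable(self, rng):
        """lambda_global = 0 on smooth features: U approaches Z (dims agree).

        Neighborhood aggregation can only reproduce targets that vary
        smoothly over the graph, which fixture embeddings do.
        """
        n = 60
        coords = CoordinateTable(rng.random((n, 2)), [f"s{i}" for i in range(n)])
        g = build_graph(coords, k=5)
        freqs = rng.normal(size=(2, 8))
        z = np.sin(coords.coords @ freqs * 3.0) + 0.05 * rng.normal(size=(n, 8))
        cfg = GATConfig(layer_dims=(8, 8), lambda_global=0.0, dropout=0.0,
                        iterations=400, seed=0)
        emb = train_gat(z, g, cfg)
        hist = emb.training_history
        assert hist[-1]["loss_local"] < 0.1 * hist[0]["loss_local"]

    def test_presets(self):
        assert LAMBDA_GLOBAL_PRESETS == {"stereo-seq": 0.08, "slide-seqv2": 0.08,
                                         "visium": 0.3, "starmap": 2.0}
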