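"""Count-model autoencoder producing the cell-type-related embedding Z.

The encoder is two ReLU layers (G -> m' -> m) applied to the normalized
expression; the decoder expands the bottleneck back to m' and emits the
parameters of a (ZI)NB distribution through per-family output heads:

* ``R`` (per-entry dispersion): exponential activation,
* ``P`` (per-gene success probability): a free per-gene logit vector
  through a sigmoid — one value per gene, shared across spots,
* ``Pi`` (per-entry zero-inflation, ZINB only): sigmoid.

Training minimizes the mean negative log-likelihood of the *raw* counts
under those parameters with Adam, full batch; the normalized matrix is
only the encoder input. ``family="auto"`` picks ZINB when the raw matrix
is more than 90% zeros (highly sparse platforms), NB otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from ._optim import Adam
from .io import CountMatrix
from .likelihoods import DistributionParams, nll_loss
from .preprocess import NormalizedExpression

#: zero fraction above which family="auto" selects ZINB
AUTO_ZINB_THRESHOLD = 0.9


@dataclass
class AEConfig:
    hidden_dim: int = 128
    bottleneck_dim: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.1
    epochs: int = 40
    family: str = "zinb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.bottleneck_dim < 1:
            raise ValueError("layer dimensions must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.family not in ("nb", "zinb", "auto"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ExpressionFeatures:
    """Bottleneck embedding Z with the training loss trace."""

    z: np.ndarray
    history: list[float] = field(default_factory=list)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class AutoEncoder:
    """Parameter container + forward pass; see module docstring."""

    def __init__(self, n_genes: int, cfg: AEConfig, family: str):
        if cfg.bottleneck_dim > n_genes:
            raise ValueError(
                f"bottleneck dim {cfg.bottleneck_dim} exceeds gene count {n_genes}")
        self.cfg = cfg
        self.family = family
        self.n_genes = n_genes
        rng = np.random.default_rng(cfg.seed)
        g, mh, mb = n_genes, cfg.hidden_dim, cfg.bottleneck_dim
        p: dict[str, Tensor] = {
            "enc_w1": Tensor(_glorot(rng, g, mh), requires_grad=True),
            "enc_b1": Tensor(np.zeros(mh), requires_grad=True),
            "enc_w2": Tensor(_glorot(rng, mh, mb), requires_grad=True),
            "enc_b2": Tensor(np.zeros(mb), requires_grad=True),
            "dec_w1": Tensor(_glorot(rng, mb, mh), requires_grad=True),
            "dec_b1": Tensor(np.zeros(mh), requires_grad=True),
            "r_w": Tensor(_glorot(rng, mh, g), requires_grad=True),
            "r_b": Tensor(np.zeros(g), requires_grad=True),
            "p_logit": Tensor(np.zeros(g), requires_grad=True),
        }
        if family == "zinb":
            p["pi_w"] = Tensor(_glorot(rng, mh, g), requires_grad=True)
            p["pi_b"] = Tensor(np.zeros(g) - 1.0, requires_grad=True)
        self.params = p

    # -- forward -----------------------------------------------------------
    def _dropout(self, t: Tensor, rng: np.random.Generator | None) -> Tensor:
        rate = self.cfg.dropout
        if rng is None or rate == 0.0:
            return t
        mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
        return t * mask

    def encode(self, xnorm: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        p = self.params
        h = ag.relu(Tensor(xnorm) @ p["enc_w1"] + p["enc_b1"])
        h = self._dropout(h, rng)
        z = ag.relu(h @ p["enc_w2"] + p["enc_b2"])
        return self._dropout(z, rng)

    def decode(self, z: Tensor) -> DistributionParams:
        p = self.params
        zp = ag.relu(z @ p["dec_w1"] + p["dec_b1"])
        r = ag.exp(ag.clip(zp @ p["r_w"] + p["r_b"], -30.0, 30.0))
        prob = ag.sigmoid(p["p_logit"])
        pi = ag.sigmoid(zp @ p["pi_w"] + p["pi_b"]) if self.family == "zinb" else None
        return DistributionParams(r=r, p=prob, pi=pi)

    def loss(self, xnorm: np.ndarray, xraw: np.ndarray,
             rng: np.random.Generator | None = None) -> Tensor:
        return nll_loss(xraw, self.decode(self.encode(xnorm, rng)), family=self.family)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: a single .npz of parameters + a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **{k: t.data for k, t in self.params.items()})
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"config": asdict(self.cfg),
                                       "family": self.family,
                                       "n_genes": self.n_genes}))

    @classmethod
    def load(cls, path: str | Path) -> "AutoEncoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        model = cls(meta["n_genes"], AEConfig(**meta["config"]), meta["family"])
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
            for k in model.params:
                model.params[k].data = data[k]
        return model


def resolve_family(family: str, xraw: CountMatrix | np.ndarray) -> str:
    """Resolve ``"auto"`` to nb/zinb from the observed zero fraction."""
    if family != "auto":
        return family
    counts = xraw.counts if isinstance(xraw, CountMatrix) else np.asarray(xraw)
    return "zinb" if np.mean(counts == 0) > AUTO_ZINB_THRESHOLD else "nb"


def build_ae(n_genes: int, cfg: AEConfig, family: str | None = None) -> AutoEncoder:
    """Freshly initialized autoencoder; identical seeds give identical weights."""
    fam = family or cfg.family
    if fam == "auto":
        raise ValueError("resolve family before building (see resolve_family)")
    return AutoEncoder(n_genes, cfg, fam)


def train_ae(xnorm: NormalizedExpression | np.ndarray, xraw: CountMatrix | np.ndarray,
             cfg: AEConfig | None = None,
             model: AutoEncoder | None = None) -> tuple[ExpressionFeatures, AutoEncoder]:
    """Full-batch Adam on the mean (ZI)NB negative log-likelihood.

    Returns the embedding from the trained encoder in evaluation mode
    (dropout off) together with the fitted model. One "iteration" is one
    full-batch gradient step.
    """
    cfg = cfg or AEConfig()
    xn = xnorm.xnorm if isinstance(xnorm, NormalizedExpression) else np.asarray(xnorm)
    xr = xraw.counts if isinstance(xraw, CountMatrix) else np.asarray(xraw)
    if xn.shape != xr.shape:
        raise ValueError(f"normalized {xn.shape} and raw {xr.shape} shapes differ")
    family = resolve_family(cfg.family, xr)
    if model is None:
        model = build_ae(xn.shape[1], cfg, family)
    rng = np.random.default_rng(cfg.seed + 1)  # dropout stream, distinct from init
    opt = Adam(list(model.params.values()), lr=cfg.learning_rate)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        loss = model.loss(xn, xr, rng)
        value = loss.item()
        if not np.isfinite(value):
            norms = {k: float(np.linalg.norm(t.data)) for k, t in model.params.items()}
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; parameter norms: {norms}")
        loss.backward()
        opt.step()
        history.append(value)
    z = model.encode(xn, rng=None).data  # eval mode
    return ExpressionFeatures(z=z, history=history), model
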