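"""Negative-binomial and zero-inflated negative-binomial log-likelihoods.

These kernels define the autoencoder reconstruction loss. The NB uses the
(r, p) parametrization

    NB(x; r, p) = Gamma(x + r) / (x! Gamma(r)) * p^r * (1 - p)^x,

so the mean is r (1 - p) / p. The ZINB mixes a point mass at zero with
probability ``pi``:

    ZINB(x; pi, r, p) = pi * I[x = 0] + (1 - pi) * NB(x; r, p).

``r`` and ``pi`` are per-entry matrices; ``p`` is one value per gene,
broadcast across spots. The at-zero ZINB term is evaluated with
log-sum-exp so it stays finite at extreme sparsity. All functions accept
either numpy arrays or autodiff :class:`~sece._autograd.Tensor` operands
for the parameters, so the exact same formulas back both the public
numerical API and the trained decoder heads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as _sp

from . import _autograd as ag
from ._autograd import Tensor

#: internal clip applied to p for gradient stability near the boundary
_P_EPS = 1e-8


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _lgamma(x):
    return ag.lgamma(x) if _is_tensor(x) else _sp.gammaln(x)


def _log(x):
    return ag.log(x) if _is_tensor(x) else np.log(x)


def _log1p(x):
    return ag.log1p(x) if _is_tensor(x) else np.log1p(x)


def _logaddexp(a, b):
    if _is_tensor(a) or _is_tensor(b):
        return ag.logaddexp(a, b)
    return np.logaddexp(a, b)


def _where(cond, a, b):
    if _is_tensor(a) or _is_tensor(b):
        return ag.where(cond, a, b)
    return np.where(cond, a, b)


def _clip_p(p):
    if _is_tensor(p):
        return ag.clip(p, _P_EPS, 1.0 - _P_EPS)
    return np.clip(p, _P_EPS, 1.0 - _P_EPS)


@dataclass
class DistributionParams:
    """Parameters of the (ZI)NB decoder output.

    ``pi`` may be ``None`` for the plain NB family. ``p`` is a length-G
    vector (one success probability per gene).
    """

    r: np.ndarray | Tensor
    p: np.ndarray | Tensor
    pi: np.ndarray | Tensor | None = None

    def validate(self) -> None:
        """Domain checks; only meaningful for concrete numpy parameters."""
        for name, arr in (("r", self.r), ("p", self.p), ("pi", self.pi)):
            if arr is None or _is_tensor(arr):
                continue
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if not _is_tensor(self.r) and np.any(np.asarray(self.r) <= 0):
            raise ValueError("dispersion r must be strictly positive")
        if not _is_tensor(self.p):
            p = np.asarray(self.p)
            if np.any(p <= 0) or np.any(p >= 1):
                raise ValueError("success parameter p must lie in the open interval (0, 1)")
        if self.pi is not None and not _is_tensor(self.pi):
            pi = np.asarray(self.pi)
            if np.any(pi < 0) or np.any(pi > 1):
                raise ValueError("zero-inflation pi must lie in [0, 1]")


_counts_cache: dict = {"src": None, "value": None}


def _check_counts(x: np.ndarray) -> np.ndarray:
    # one-slot cache: training loops revalidate the same matrix every epoch.
    # The source object is held strongly so identity comparison is sound.
    if x is _counts_cache["src"]:
        return _counts_cache["value"]
    arr = np.asarray(x)
    if np.any(arr < 0) or not np.allclose(arr, np.rint(arr)):
        raise ValueError("counts must be nonnegative integers")
    out = arr.astype(np.float64)
    _counts_cache["src"] = x
    _counts_cache["value"] = out
    return out


def nb_log_pmf(x: np.ndarray, params: DistributionParams):
    """Elementwise log NB(x; r, p); finite on the whole valid domain."""
    params.validate()
    x = _check_counts(x)
    r, p = params.r, _clip_p(params.p)
    if _is_tensor(r) or _is_tensor(p):
        return _nb_log_pmf_fused(x, Tensor._lift(r), Tensor._lift(p))
    return (_lgamma(x + r) - _sp.gammaln(x + 1.0) - _lgamma(r)
            + r * _log(p) + x * _log1p(-p))


def _nb_log_pmf_fused(x: np.ndarray, r: Tensor, p: Tensor) -> Tensor:
    """Autodiff NB log-pmf exploiting count sparsity.

    For x = 0 the pmf collapses to r log p, so the gamma-function terms
    (and their digamma gradients) are evaluated only on the nonzero
    entries. Identical values and gradients to the dense formula.
    """
    nz = x > 0
    xnz = x[nz]
    r_full = np.broadcast_to(r.data, x.shape)
    p_full = np.broadcast_to(p.data, x.shape)
    rnz = r_full[nz]
    out = r_full * np.log(p_full)
    out[nz] += (_sp.gammaln(xnz + rnz) - _sp.gammaln(xnz + 1.0) - _sp.gammaln(rnz)
                + xnz * np.log1p(-p_full[nz]))

    def backward(g):
        dr = np.log(p_full) * g
        gnz = g[nz]
        np.add.at(dr, np.nonzero(nz), gnz * (_sp.digamma(xnz + rnz) - _sp.digamma(rnz)))
        dp = (r_full / p_full) * g
        np.add.at(dp, np.nonzero(nz), -gnz * xnz / (1.0 - p_full[nz]))
        return dr, dp

    return Tensor._node(out, (r, p), backward)


def zinb_log_pmf(x: np.ndarray, params: DistributionParams):
    """Elementwise log ZINB(x; pi, r, p).

    At x = 0 the mixture term log(pi + (1-pi) NB(0)) is computed by
    log-sum-exp of {log pi, log(1-pi) + r log p}. The exact edge cases
    pi = 0 and pi = 1 are honored: pi = 1 gives probability 1 at zero and
    -inf (log of zero) at any positive count.
    """
    if params.pi is None:
        raise ValueError("zinb_log_pmf requires pi")
    x = _check_counts(x)
    nb = nb_log_pmf(x, params)
    pi = params.pi
    with np.errstate(divide="ignore"):
        log_pi = _log(pi)
        log_1mpi = _log1p(-pi)
    at_zero = _logaddexp(log_pi, log_1mpi + nb)
    nonzero = log_1mpi + nb
    if not _is_tensor(nonzero):
        # (1-pi)=0 with nb=-inf would give nan; the mixture weight is zero
        nonzero = np.where(np.isnan(nonzero), -np.inf, nonzero)
        at_zero = np.where(np.isnan(at_zero), np.broadcast_to(log_pi, at_zero.shape), at_zero)
    return _where(x == 0, at_zero, nonzero)


def nll_loss(x: np.ndarray, params: DistributionParams, family: str = "zinb"):
    """Mean negative log-likelihood over all N×G entries.

    The mean (rather than sum) reduction keeps the optimizer learning
    rate transferable across dataset sizes.
    """
    if family not in ("nb", "zinb"):
        raise ValueError(f"unknown family {family!r}")
    logp = zinb_log_pmf(x, params) if family == "zinb" else nb_log_pmf(x, params)
    x = np.asarray(x)
    shape = logp.shape if not _is_tensor(logp) else logp.data.shape
    if shape != x.shape:
        raise ValueError(f"shape mismatch: counts {x.shape} vs log-pmf {shape}")
    if _is_tensor(logp):
        return -logp.mean()
    return float(-np.mean(logp))
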